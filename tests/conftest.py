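import numpy as np
import pytest

import lattiq as lq
from lattiq import reference as ref


@pytest.fixture(scope="session")
def design7():
    return lq.make_design(7, 2)


@pytest.fixture(scope="session")
def design3():
    return lq.make_design(3, 2)


@pytest.fixture(scope="session")
def projectors7(design7):
    from lattiq.anova import sequential_projectors

    return sequential_projectors(design7)


@pytest.fixture(scope="session")
def dth_model():
    """Single-trait model at the published days-to-heading scale."""
    return ref.reference_genetic_model(("DTH",), sigma2_b=3.0)


@pytest.fixture(scope="session")
def dth_trial(design7, dth_model):
    return lq.simulate_trial(design7, dth_model, seed=42)


@pytest.fixture(scope="session")
def multitrait_trial(design7):
    """Five-trait trial with the published genetic correlation structure."""
    model = ref.reference_genetic_model(
        ("DTH", "DTM", "PLHT", "NFT", "GY"), sigma2_b=3.0
    )
    return model, lq.simulate_trial(design7, model, seed=271828)


def random_plot_table(design, n_traits=1, seed=0, names=None):
    """Unstructured noise table on a given design (for algebraic identities)."""
    rng = np.random.default_rng(seed)
    frame = design.to_frame()
    names = names or [f"T{i+1}" for i in range(n_traits)]
    for t in names:
        frame[t] = rng.normal(10.0, 2.0, size=len(frame))
    return lq.PlotTable(data=frame, traits=tuple(names))
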