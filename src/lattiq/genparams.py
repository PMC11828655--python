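"""Variance components and derived genetic parameters.

From the expected mean squares of a simple-lattice intra-block ANOVA the
genotypic variance is

    sigma2_g = (k + 1) * (Msg - Mse) / (k * r)

with Msg the accession mean square, Mse the intra-block residual mean
square, k the block size and r the number of replications; the
environmental variance is Mse and the phenotypic variance their sum.
Derived parameters follow the standard germplasm-evaluation formulas:

    GCV% = 100 * sqrt(sigma2_g) / mean
    PCV% = 100 * sqrt(sigma2_p) / mean
    H2%  = 100 * sigma2_g / sigma2_p          (broad sense)
    GA   = k_sel * sqrt(sigma2_p) * H2        (H2 as a proportion)
    GAM% = 100 * GA / mean

with ``k_sel`` the standardized selection differential (2.063 at 5%
selection intensity).  Each coefficient is classified as low / moderate /
high using configurable thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VarianceComponents",
    "GeneticParams",
    "CategoryThresholds",
    "variance_components",
    "derived_parameters",
    "K_SEL_5PCT",
]

K_SEL_5PCT = 2.063  # standardized selection differential at 5% intensity


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    truncated: bool = False  # Msg < Mse, genotypic variance clipped at 0

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_e


@dataclass(frozen=True)
class CategoryThresholds:
    """Cutoffs for low / moderate / high classification (percent scales).

    ``cv`` covers GCV and PCV; ``h2`` broad-sense heritability; ``gam``
    genetic advance as percent of the mean.
    """

    cv: tuple[float, float] = (10.0, 20.0)
    h2: tuple[float, float] = (30.0, 60.0)
    gam: tuple[float, float] = (10.0, 20.0)

    @staticmethod
    def classify(value: float, cuts: tuple[float, float]) -> str:
        lo, hi = cuts
        if value < lo:
            return "low"
        if value <= hi:
            return "moderate"
        return "high"


@dataclass(frozen=True)
class GeneticParams:
    """Per-trait genetic parameters with categorical labels."""

    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    gcv_percent: float
    pcv_percent: float
    h2_percent: float
    ga: float
    gam_percent: float
    truncated: bool
    categories: dict = field(default_factory=dict)


def variance_components(
    msg: float, mse: float, k: int, r: int
) -> VarianceComponents:
    """Genotypic, environmental and phenotypic variance from lattice mean squares.

    A negative moment estimate (Msg < Mse) is truncated to zero and
    flagged, since the square roots downstream require non-negativity.
    """
    if msg < 0 or mse < 0:
        raise ValueError(f"mean squares must be non-negative, got msg={msg}, mse={mse}")
    if k < 2:
        raise ValueError(f"block size k must be >= 2, got {k}")
    if r < 2:
        raise ValueError(f"replication count r must be >= 2, got {r}")
    raw = (k + 1) * (msg - mse) / (k * r)
    truncated = raw < 0
    return VarianceComponents(
        sigma2_g=max(raw, 0.0), sigma2_e=float(mse), truncated=truncated
    )


def derived_parameters(
    vc: VarianceComponents,
    mean: float,
    k_sel: float = K_SEL_5PCT,
    thresholds: CategoryThresholds | None = None,
) -> GeneticParams:
    """Coefficients of variation, heritability and genetic advance."""
    if mean <= 0:
        raise ValueError(f"trait mean must be positive, got {mean}")
    thresholds = thresholds or CategoryThresholds()
    s2g, s2p = vc.sigma2_g, vc.sigma2_p
    gcv = 100.0 * np.sqrt(s2g) / mean
    pcv = 100.0 * np.sqrt(s2p) / mean
    h2 = 100.0 * s2g / s2p if s2p > 0 else 0.0
    ga = k_sel * np.sqrt(s2p) * (h2 / 100.0)
    gam = 100.0 * ga / mean
    cats = {
        "gcv": CategoryThresholds.classify(gcv, thresholds.cv),
        "pcv": CategoryThresholds.classify(pcv, thresholds.cv),
        "h2": CategoryThresholds.classify(h2, thresholds.h2),
        "gam": CategoryThresholds.classify(gam, thresholds.gam),
    }
    return GeneticParams(
        sigma2_g=float(s2g),
        sigma2_e=float(vc.sigma2_e),
        sigma2_p=float(s2p),
        gcv_percent=float(gcv),
        pcv_percent=float(pcv),
        h2_percent=float(h2),
        ga=float(ga),
        gam_percent=float(gam),
        truncated=vc.truncated,
        categories=cats,
    )
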