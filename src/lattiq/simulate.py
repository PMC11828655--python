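"""Synthetic plot-level data for a simple lattice trial.

The generator draws from the variance-component model the intra-block
analysis assumes:

    y[a, j, v] = mu_v + rep_j_v + block(j, b)_v + G[a, v] + E[a, j, v]

with genotype effects G drawn once per trial from a multivariate normal
with covariance ``diag(sg) @ Rg @ diag(sg)``, incomplete-block effects
i.i.d. normal with variance ``sigma2_b`` (independent across traits), and
plot errors E multivariate normal from the error correlation ``Re``.
Replication effects are fixed shifts.  Under this model the phenotypic
variance of a genotype mean over r replications is
``sigma2_g + sigma2_e / r`` and the lattice ANOVA estimators are unbiased
for the planted components, which is what parameter-recovery tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import TrialDesign
from .errors import ModelError, SchemaError

__all__ = ["GeneticModel", "PlotTable", "simulate_trial", "true_values"]

_PSD_TOL = 1e-10


def _check_corr(name: str, m: np.ndarray, t: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (t, t):
        raise ModelError(f"{name} must be {t}x{t}, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ModelError(f"{name} is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ModelError(f"{name} does not have a unit diagonal")
    if np.linalg.eigvalsh(m).min() < -_PSD_TOL:
        raise ModelError(f"{name} is not positive semi-definite")
    return m


@dataclass(frozen=True)
class GeneticModel:
    """Generating model for one simulated trial.

    All per-trait vectors must have one entry per name in ``trait_names``;
    ``rep_effects`` has shape (r, t).
    """

    trait_names: tuple[str, ...]
    mu: np.ndarray
    sigma2_g: np.ndarray
    Rg: np.ndarray
    sigma2_b: np.ndarray
    sigma2_e: np.ndarray
    Re: np.ndarray
    rep_effects: np.ndarray

    def __post_init__(self):
        t = len(self.trait_names)
        for nm in ("mu", "sigma2_g", "sigma2_b", "sigma2_e"):
            v = np.asarray(getattr(self, nm), dtype=float)
            if v.shape != (t,):
                raise ModelError(f"{nm} must have length {t}, got shape {v.shape}")
            object.__setattr__(self, nm, v)
        for nm in ("sigma2_g", "sigma2_b", "sigma2_e"):
            if (getattr(self, nm) < 0).any():
                raise ModelError(f"{nm} contains a negative variance")
        object.__setattr__(self, "Rg", _check_corr("Rg", self.Rg, t))
        object.__setattr__(self, "Re", _check_corr("Re", self.Re, t))
        re_ = np.asarray(self.rep_effects, dtype=float)
        if re_.ndim != 2 or re_.shape[1] != t:
            raise ModelError(
                f"rep_effects must be (r, {t}), got shape {re_.shape}"
            )
        object.__setattr__(self, "rep_effects", re_)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @classmethod
    def single_trait(
        cls,
        name: str = "Y",
        mu: float = 0.0,
        sigma2_g: float = 1.0,
        sigma2_b: float = 0.0,
        sigma2_e: float = 1.0,
        r: int = 2,
        rep_effects=None,
    ) -> "GeneticModel":
        """Convenience constructor for one-trait models."""
        eye = np.eye(1)
        reps = np.zeros((r, 1)) if rep_effects is None else np.asarray(
            rep_effects, float
        ).reshape(r, 1)
        return cls(
            trait_names=(name,),
            mu=np.array([mu]),
            sigma2_g=np.array([sigma2_g]),
            Rg=eye,
            sigma2_b=np.array([sigma2_b]),
            sigma2_e=np.array([sigma2_e]),
            Re=eye.copy(),
            rep_effects=reps,
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneticModel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        traits = tuple(cfg["trait_names"])
        t = len(traits)
        r = int(cfg.get("r", 2))
        reps = np.asarray(cfg.get("rep_effects", np.zeros((r, t))), float)
        return cls(
            trait_names=traits,
            mu=np.asarray(cfg["mu"], float),
            sigma2_g=np.asarray(cfg["sigma2_g"], float),
            Rg=np.asarray(cfg.get("Rg", np.eye(t)), float),
            sigma2_b=np.asarray(cfg["sigma2_b"], float),
            sigma2_e=np.asarray(cfg["sigma2_e"], float),
            Re=np.asarray(cfg.get("Re", np.eye(t)), float),
            rep_effects=reps,
        )

    def to_yaml(self, path) -> None:
        cfg = {
            "trait_names": list(self.trait_names),
            "mu": self.mu.tolist(),
            "sigma2_g": self.sigma2_g.tolist(),
            "Rg": self.Rg.tolist(),
            "sigma2_b": self.sigma2_b.tolist(),
            "sigma2_e": self.sigma2_e.tolist(),
            "Re": self.Re.tolist(),
            "r": int(self.rep_effects.shape[0]),
            "rep_effects": self.rep_effects.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclass
class PlotTable:
    """Tidy plot-level observations keyed by (accession, replication, block).

    ``data`` holds one row per plot with the key columns followed by one
    numeric column per trait.  ``balanced`` is set when every
    (accession, replication) cell is present exactly once with no missing
    trait values.
    """

    data: pd.DataFrame
    traits: tuple[str, ...]
    balanced: bool = field(default=False)

    KEY_COLUMNS = ("accession", "replication", "block")

    def __post_init__(self):
        missing = [c for c in self.KEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"plot table is missing column(s): {missing}")
        absent = [t for t in self.traits if t not in self.data.columns]
        if absent:
            raise SchemaError(f"plot table is missing trait column(s): {absent}")
        self.traits = tuple(self.traits)

    def check_balanced(self, design: TrialDesign) -> None:
        """Raise unless every (accession, replication) cell appears once."""
        from .errors import BalanceError

        counts = self.data.groupby(["accession", "replication"]).size()
        dup = counts[counts > 1]
        if len(dup):
            raise SchemaError(
                f"duplicate (accession, replication) cells: {list(dup.index)}"
            )
        expected = {
            (a, rep)
            for rep in range(1, design.r + 1)
            for a in range(1, design.g + 1)
        }
        present = set(counts.index)
        missing = sorted(expected - present)
        if missing:
            raise BalanceError(
                f"missing (accession, replication) cells: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        if self.data[list(self.traits)].isna().any().any():
            raise BalanceError("plot table contains missing trait values")
        self.balanced = True

    def trait_vector(self, trait: str, order: pd.DataFrame) -> np.ndarray:
        """Trait values aligned to the plot order of ``order`` (accession, replication)."""
        merged = order.merge(
            self.data, on=["accession", "replication"], how="left", suffixes=("", "_y")
        )
        return merged[trait].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        cols = list(self.KEY_COLUMNS) + list(self.traits)
        self.data[cols].to_csv(path, index=False)


def simulate_trial(
    design: TrialDesign, model: GeneticModel, seed: int
) -> PlotTable:
    """Draw one complete trial from the generating model.

    The same (design, model, seed) triple always produces an identical
    table.  Draw order is fixed: genotype effects, then block effects, then
    plot errors, each from an independent stream of one seeded generator.
    """
    rng = np.random.default_rng(seed)
    g, r, k, t = design.g, design.r, design.k, model.n_traits

    sg = np.sqrt(model.sigma2_g)
    cov_g = sg[:, None] * model.Rg * sg[None, :]
    G = rng.multivariate_normal(np.zeros(t), cov_g, size=g, method="svd")

    # one independent draw per (rep, block, trait); no cross-trait block term
    B = rng.normal(0.0, 1.0, size=(r, k, t)) * np.sqrt(model.sigma2_b)[None, None, :]

    se = np.sqrt(model.sigma2_e)
    cov_e = se[:, None] * model.Re * se[None, :]
    E = rng.multivariate_normal(np.zeros(t), cov_e, size=g * r, method="svd")

    rows = []
    idx = 0
    for rep in range(1, r + 1):
        for blk in range(1, k + 1):
            for acc in design.layout[(rep, blk)]:
                y = (
                    model.mu
                    + model.rep_effects[rep - 1]
                    + B[rep - 1, blk - 1]
                    + G[acc - 1]
                    + E[idx]
                )
                rows.append((acc, rep, blk, *y))
                idx += 1
    frame = pd.DataFrame(
        rows, columns=["accession", "replication", "block", *model.trait_names]
    )
    table = PlotTable(data=frame, traits=model.trait_names)
    table.check_balanced(design)
    return table


def true_values(model: GeneticModel) -> dict:
    """Generating ground truth used by recovery tests.

    Returns per-trait genotypic, environmental and phenotypic variances
    (``sigma2_p = sigma2_g + sigma2_e``) plus the planted genotypic
    correlation matrix.
    """
    return {
        "trait_names": model.trait_names,
        "sigma2_g": model.sigma2_g.copy(),
        "sigma2_e": model.sigma2_e.copy(),
        "sigma2_p": model.sigma2_g + model.sigma2_e,
        "rg": model.Rg.copy(),
    }
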