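"""Path-coefficient analysis: direct and indirect effects on yield.

Given the correlation matrix ``Rxx`` among predictor traits and the
vector ``rxy`` of their correlations with yield, the direct effects
(path coefficients) P solve the normal equations

    Rxx @ P = rxy

The indirect effect of trait i via trait j is ``P_j * r_ij``; each row
of direct-plus-indirect effects sums back to the trait's correlation
with yield.  The residual effect is reported as

    residual_effect = 1 - sum_i P_i * r_iy

(the share of yield variation not explained by the predictor system);
its square root, the classical residual path coefficient, is also kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SelectionError, SingularityError

__all__ = [
    "PathResult",
    "select_predictors",
    "path_coefficients",
    "effect_category",
]

_EFFECT_CUTS = (
    (0.095, "negligible"),
    (0.195, "low"),
    (0.295, "moderate"),
    (1.0, "high"),
)


def effect_category(value: float) -> str:
    """Magnitude class of a path effect: negligible, low, moderate, high, very high."""
    a = abs(value)
    for cut, label in _EFFECT_CUTS:
        if a <= cut:
            return label
    return "very high"


@dataclass(frozen=True)
class PathResult:
    level: str  # "genotypic" or "phenotypic"
    predictors: tuple[str, ...]
    direct: pd.Series
    indirect: pd.DataFrame  # cell [i, j] = P_j * r_ij for i != j; diagonal = direct
    reconstructed_r: pd.Series  # row sums; equals rxy for solver-produced P
    rxy: pd.Series
    residual_effect: float
    residual_path: float
    condition_number: float
    categories: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Effects table: predictors as rows, final column the yield correlation."""
        out = self.indirect.copy()
        out["r_with_yield"] = self.rxy
        return out


def select_predictors(
    corr,
    yield_trait: str,
    level: str = "genotypic",
    alpha: float = 0.05,
    override: list[str] | None = None,
) -> list[str]:
    """Traits significantly correlated with yield at the given level.

    ``corr`` is a :class:`~lattiq.assoc.CorrMatrices`.  An explicit
    ``override`` list bypasses the significance screen (order preserved).
    """
    if yield_trait not in corr.traits:
        raise SelectionError(f"yield trait {yield_trait!r} absent from matrices")
    if override is not None:
        return [t for t in override if t != yield_trait]
    sig = corr.sig_g if level == "genotypic" else corr.sig_p
    chosen = [
        t
        for t in corr.traits
        if t != yield_trait and np.isfinite(sig.loc[t, yield_trait])
        and sig.loc[t, yield_trait] <= alpha
    ]
    if not chosen:
        raise SelectionError(
            f"no trait is significantly correlated with {yield_trait!r} "
            f"at alpha={alpha} ({level} level)"
        )
    return chosen


def path_coefficients(
    Rxx: np.ndarray | pd.DataFrame,
    rxy: np.ndarray | pd.Series,
    predictors: list[str] | None = None,
    level: str = "genotypic",
) -> PathResult:
    """Solve the path system and assemble direct / indirect effects.

    ``Rxx`` must be symmetric with unit diagonal, ordered like ``rxy``.
    A negative residual effect (possible when the inputs come from
    independently rounded correlations) is reported with a warning, not
    clamped.
    """
    R = np.asarray(Rxx, dtype=float)
    r = np.asarray(rxy, dtype=float).ravel()
    if predictors is None:
        if isinstance(Rxx, pd.DataFrame):
            predictors = list(Rxx.index)
        else:
            predictors = [f"X{i+1}" for i in range(len(r))]
    p = len(predictors)
    if R.shape != (p, p) or len(r) != p:
        raise ValueError(
            f"shape mismatch: Rxx {R.shape}, rxy {len(r)}, predictors {p}"
        )
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("Rxx must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("Rxx must have a unit diagonal")

    cond = float(np.linalg.cond(R))
    if not np.isfinite(cond) or cond > 1e12:
        off = np.abs(R - np.eye(p))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise SingularityError(
            f"predictor correlation matrix is singular; most collinear pair: "
            f"({predictors[i]}, {predictors[j]}) with r={R[i, j]:.4f}"
        )
    if cond > 1e3:
        warnings.warn(
            f"ill-conditioned predictor correlation matrix (cond={cond:.3g}); "
            "path coefficients may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    P = np.linalg.solve(R, r)

    indirect = R * P[None, :]  # cell [i, j] = P_j * r_ij; diagonal = P_i
    recon = indirect.sum(axis=1)
    residual_effect = float(1.0 - P @ r)
    if residual_effect < 0:
        warnings.warn(
            f"negative residual effect ({residual_effect:.4f}); the correlation "
            "inputs are mutually inconsistent (e.g. independently rounded)",
            RuntimeWarning,
            stacklevel=2,
        )
    residual_path = float(np.sqrt(max(residual_effect, 0.0)))

    idx = list(predictors)
    cats = pd.DataFrame(
        [[effect_category(v) for v in row] for row in indirect],
        index=idx,
        columns=idx,
    )
    return PathResult(
        level=level,
        predictors=tuple(predictors),
        direct=pd.Series(P, index=idx, name="direct"),
        indirect=pd.DataFrame(indirect, index=idx, columns=idx),
        reconstructed_r=pd.Series(recon, index=idx, name="reconstructed_r"),
        rxy=pd.Series(r, index=idx, name="r_with_yield"),
        residual_effect=residual_effect,
        residual_path=residual_path,
        condition_number=cond,
        categories=cats,
    )
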