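"""Principal component analysis of the trait correlation matrix.

Accession means are z-scored per trait (n - 1 denominator, shared with
the diversity module) and the correlation matrix eigendecomposed.
Eigenvalues sum to the number of traits; the variance explained by a
component is 100 * eigenvalue / t.  Components with eigenvalue > 1 are
retained under the Kaiser criterion.  Eigenvector sign is arbitrary, so
each loading column is flipped to make its largest-magnitude entry
positive, which fixes the orientation deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import standardize
from .errors import LattiqError

__all__ = ["PCAResult", "pca_correlation"]


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # descending
    loadings: pd.DataFrame  # trait x component, orthonormal columns
    var_explained_percent: np.ndarray
    cumulative_percent: np.ndarray
    scores: pd.DataFrame  # accession x component
    retained: tuple[str, ...]  # Kaiser rule: eigenvalue > 1

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.loadings.columns)

    def summary(self) -> pd.DataFrame:
        """Components as rows: eigenvector entries, eigenvalue, %var, cum %."""
        out = self.loadings.T.copy()
        out["eigenvalue"] = self.eigenvalues
        out["var_explained_percent"] = self.var_explained_percent
        out["cumulative_percent"] = self.cumulative_percent
        return out

    def biplot_coordinates(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(accession scores, trait loadings scaled by sqrt(eigenvalue))."""
        scale = np.sqrt(self.eigenvalues)
        arrows = self.loadings * scale[None, :]
        return self.scores.copy(), arrows


def pca_correlation(means: pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the trait correlation matrix of accession means."""
    n, t = means.shape
    if n < 3:
        raise LattiqError(f"PCA needs at least 3 accessions, got {n}")
    z = standardize(means)
    corr = (z.to_numpy().T @ z.to_numpy()) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    idx = np.argsort(evals)[::-1]
    evals = evals[idx]
    evecs = evecs[:, idx]
    if t > n - 1:
        warnings.warn(
            f"more traits ({t}) than accessions minus one ({n - 1}): "
            "trailing eigenvalues are zero (rank deficiency)",
            RuntimeWarning,
            stacklevel=2,
        )
        evals = np.where(np.abs(evals) < 1e-10, 0.0, evals)

    # deterministic orientation: largest-magnitude loading positive
    for j in range(t):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]

    comps = tuple(f"PC{j+1}" for j in range(t))
    loadings = pd.DataFrame(evecs, index=means.columns, columns=comps)
    scores = pd.DataFrame(
        z.to_numpy() @ evecs, index=means.index, columns=comps
    )
    var_pct = 100.0 * evals / t
    return PCAResult(
        eigenvalues=evals,
        loadings=loadings,
        var_explained_percent=var_pct,
        cumulative_percent=np.cumsum(var_pct),
        scores=scores,
        retained=tuple(c for c, ev in zip(comps, evals) if ev > 1.0),
    )
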