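"""Intra-block ANOVA of a simple lattice.

The per-trait analysis is the classical sequential (type-I) partition

    grand mean -> replication -> block-within-replication (unadjusted)
               -> accession (adjusted for blocks)
               -> intra-block residual

computed by incremental least-squares projection onto nested column
spaces.  Fitting accessions after blocks makes the accession mean square
the intra-block (block-adjusted) one, whose expectation under the
random-block model is sigma2_e + (k*r/(k+1)) * sigma2_g; the
(k+1)/(k*r) moment coefficient used downstream is unbiased exactly for
this ordering (the unadjusted accession mean square would inflate the
genotypic variance by (k+1)/k plus block leakage).  The accession F-test
uses the intra-block residual mean square; no inter-block information is
recovered.  For a k x k lattice with two replications the degrees of
freedom are 1, k**2 - 1, 2(k - 1) and n - k**2 - 2k + 1 —
e.g. (1, 48, 12, 36) at k = 7.

Adjusted accession means come from the full fixed-effects fit
(replication + block-within-replication + accession, sum-to-zero coding);
an adjusted mean is the grand mean plus the accession effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orth

from .design import TrialDesign
from .errors import DegenerateDesignError, LattiqError
from .simulate import PlotTable

__all__ = [
    "AnovaTable",
    "AccessionMeans",
    "anova_table",
    "adjusted_means",
    "tukey_hsd",
    "sequential_projectors",
    "significance_stars",
]

# fit order (blocks before accessions, so accessions are block-adjusted);
# tables are displayed with accessions before blocks, the conventional layout
FIT_SOURCES = ("replication", "block_within_rep", "accession", "residual")
SOURCES = ("replication", "accession", "block_within_rep", "residual")


@dataclass(frozen=True)
class AnovaTable:
    """Sequential ANOVA partition for one trait."""

    trait: str
    table: pd.DataFrame  # rows: SOURCES; columns: df, SS, MS, F, p
    grand_mean: float
    cv_percent: float

    @property
    def msg(self) -> float:
        """Accession (genotype) mean square."""
        return float(self.table.loc["accession", "MS"])

    @property
    def mse(self) -> float:
        """Intra-block residual mean square."""
        return float(self.table.loc["residual", "MS"])

    @property
    def df_error(self) -> int:
        return int(self.table.loc["residual", "df"])


@dataclass(frozen=True)
class AccessionMeans:
    """Lattice-adjusted accession means for one trait."""

    trait: str
    means: pd.Series  # indexed by accession id
    grand_mean: float
    sem: float  # standard error of an adjusted accession mean


def _plot_order(design: TrialDesign) -> pd.DataFrame:
    return design.to_frame()


def _dummies(values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    return (values[:, None] == levels[None, :]).astype(float)


def _design_matrices(design: TrialDesign):
    """Indicator blocks for the sequential fit, in fixed plot order."""
    order = _plot_order(design)
    acc = order["accession"].to_numpy()
    rep = order["replication"].to_numpy()
    blk = order["block"].to_numpy()
    n = len(order)

    X_mean = np.ones((n, 1))
    X_rep = _dummies(rep, np.arange(1, design.r + 1))
    X_acc = _dummies(acc, np.arange(1, design.g + 1))
    # blocks nested in replications: one column per (rep, block)
    rb = rep * 1000 + blk
    rb_levels = np.array(
        sorted({r_ * 1000 + b for (r_, b) in design.layout.keys()})
    )
    X_blk = _dummies(rb, rb_levels)
    return order, [X_mean, X_rep, X_blk, X_acc]


def sequential_projectors(design: TrialDesign):
    """Orthonormal bases Q_0 ⊂ Q_1 ⊂ ... of the nested model spaces.

    Returns (plot order, [Q_mean, Q_mean+rep, Q_+accession, Q_+blocks]).
    The projection onto the increment between stage i-1 and i gives that
    source's sum of squares; the same bilinear form gives cross-products
    for the covariance analysis.
    """
    order, blocks = _design_matrices(design)
    qs = []
    X = np.empty((len(order), 0))
    for b in blocks:
        X = np.hstack([X, b])
        qs.append(orth(X))
    return order, qs


def _seq_ss(qs, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Sequential cross-products x' (H_i - H_{i-1}) y and the residual CP."""
    cps = []
    prev_x = np.zeros_like(x)
    prev_y = np.zeros_like(y)
    for q in qs:
        hx = q @ (q.T @ x)
        hy = q @ (q.T @ y)
        cps.append(float((hx - prev_x) @ y))
        prev_x, prev_y = hx, hy
    resid = float((x - prev_x) @ y)
    return np.array(cps[1:]), resid  # drop grand-mean stage


def sequential_crossproducts(
    design: TrialDesign, x: np.ndarray, y: np.ndarray, qs=None
) -> dict[str, float]:
    """Type-I cross-products of two aligned plot vectors, by source."""
    if qs is None:
        _, qs = sequential_projectors(design)
    cps, resid = _seq_ss(qs, x, y)
    return dict(zip(FIT_SOURCES[:3], cps)) | {"residual": resid}


def _dfs(design: TrialDesign, qs) -> list[int]:
    ranks = [q.shape[1] for q in qs]
    dfs = [ranks[0]] + [ranks[i] - ranks[i - 1] for i in range(1, len(ranks))]
    n = design.n_plots
    dfs.append(n - ranks[-1])
    return dfs[1:]  # drop the grand-mean df


def anova_table(
    plots: PlotTable, design: TrialDesign, trait: str, qs=None
) -> AnovaTable:
    """Intra-block ANOVA of one trait.

    ``qs`` may carry precomputed projectors from
    :func:`sequential_projectors` when several traits share a design.
    """
    plots.check_balanced(design)
    if qs is None:
        order, qs = sequential_projectors(design)
    else:
        order = _plot_order(design)
    y = plots.trait_vector(trait, order)
    dfs = _dfs(design, qs)
    if dfs[-1] < 1:
        raise DegenerateDesignError("no residual degrees of freedom")
    ss, ss_res = _seq_ss(qs, y, y)
    ss = np.append(ss, ss_res)
    ms = ss / np.array(dfs, dtype=float)
    mse = ms[-1]
    fvals = np.append(ms[:-1] / mse, np.nan)
    pvals = np.array(
        [
            stats.f.sf(f, d, dfs[-1]) if np.isfinite(f) else np.nan
            for f, d in zip(fvals, dfs)
        ]
    )
    table = pd.DataFrame(
        {"df": dfs, "SS": ss, "MS": ms, "F": fvals, "p": pvals},
        index=list(FIT_SOURCES),
    ).reindex(list(SOURCES))
    grand_mean = float(y.mean())
    cv = 100.0 * np.sqrt(mse) / grand_mean if grand_mean != 0 else np.nan
    return AnovaTable(trait=trait, table=table, grand_mean=grand_mean, cv_percent=cv)


def _sum_coded(design: TrialDesign):
    """Full-rank sum-to-zero design matrix for the complete fixed fit.

    Columns: intercept | rep (r-1) | block-within-rep (r*(k-1)) |
    accession (g-1).  Every non-intercept column sums to zero over plots,
    so the intercept estimate equals the plot grand mean.
    """
    order = _plot_order(design)
    rep = order["replication"].to_numpy()
    blk = order["block"].to_numpy()
    acc = order["accession"].to_numpy()
    n = len(order)
    k, r, g = design.k, design.r, design.g

    cols = [np.ones(n)]
    for j in range(1, r):
        cols.append((rep == j).astype(float) - (rep == r).astype(float))
    for rj in range(1, r + 1):
        in_rep = rep == rj
        for b in range(1, k):
            cols.append(in_rep * ((blk == b).astype(float) - (blk == k).astype(float)))
    for a in range(1, g):
        cols.append((acc == a).astype(float) - (acc == g).astype(float))
    return order, np.column_stack(cols)


def adjusted_means(
    plots: PlotTable, design: TrialDesign, trait: str
) -> AccessionMeans:
    """Lattice-adjusted accession means for one trait.

    The accession effect is taken from the full least-squares fit with
    replication and block-within-replication terms; with zero block
    variance the adjusted means coincide with the raw per-accession means.
    """
    plots.check_balanced(design)
    order, X = _sum_coded(design)
    y = plots.trait_vector(trait, order)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    g = design.g
    tau = beta[-(g - 1):]
    effects = np.append(tau, -tau.sum())
    grand = float(beta[0])
    means = pd.Series(grand + effects, index=np.arange(1, g + 1), name=trait)

    # SEM of an adjusted mean: var(intercept + tau_a) averaged over accessions
    n = X.shape[0]
    dof = n - X.shape[1]
    mse = float(((y - X @ beta) ** 2).sum() / dof) if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    L = np.zeros((g, X.shape[1]))
    L[:, 0] = 1.0
    L[: g - 1, -(g - 1):] = np.eye(g - 1)
    L[g - 1, -(g - 1):] = -1.0
    var_means = np.einsum("ij,jk,ik->i", L, xtx_inv, L)
    sem = float(np.sqrt(mse * var_means.mean()))
    return AccessionMeans(trait=trait, means=means, grand_mean=grand, sem=sem)


def tukey_hsd(
    means: AccessionMeans, mse: float, df_error: int, alpha: float = 0.05, r: int = 2
) -> pd.DataFrame:
    """Compact letter display from Tukey's honest significant difference.

    HSD = q(1-alpha; g, df_error) * sqrt(mse / r).  Accessions are sorted
    by descending mean and letters assigned greedily: each maximal run of
    means whose spread is below the HSD shares a letter.
    """
    if mse <= 0:
        raise ValueError(f"residual mean square must be positive, got {mse}")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    g = len(means.means)
    q = stats.studentized_range.ppf(1 - alpha, g, df_error)
    hsd = q * np.sqrt(mse / r)

    ordered = means.means.sort_values(ascending=False, kind="mergesort")
    vals = ordered.to_numpy()
    # window starting at i extends while the spread stays within the HSD;
    # a window is kept only if it is not contained in its predecessor
    maximal = []
    prev_end = 0
    for i in range(g):
        j = i + 1
        while j < g and vals[i] - vals[j] <= hsd:
            j += 1
        if j > prev_end:
            maximal.append((i, j))
            prev_end = j
    letters = ["" for _ in range(g)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (i, j) in enumerate(maximal):
        ch = alphabet[li % len(alphabet)] * (li // len(alphabet) + 1)
        for p in range(i, j):
            letters[p] += ch
    out = pd.DataFrame(
        {"mean": vals, "group": letters}, index=ordered.index
    )
    out.attrs["hsd"] = float(hsd)
    out.attrs["alpha"] = alpha
    return out


def significance_stars(p: float) -> str:
    """Conventional star codes: *** <0.001, ** <0.01, * <0.05, else ns."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
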