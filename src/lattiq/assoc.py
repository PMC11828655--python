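"""Genotypic and phenotypic covariance components and trait correlations.

Cross-products are the bilinear extension of the sequential lattice
ANOVA: with P_s the projector onto source s's increment,
CP_s(x, y) = x' P_s y and MCP_s = CP_s / df_s.  The genotypic covariance
between two traits uses the same moment estimator as the genotypic
variance,

    cov_g = (k + 1) * (MCP_accession - MCP_residual) / (k * r)
    cov_e = MCP_residual
    cov_p = cov_g + cov_e

and the correlations are cov_g / sqrt(s2g_x * s2g_y) (genotypic) and
cov_p / sqrt(s2p_x * s2p_y) (phenotypic).  Because the estimators are
ratios of moment estimates, a genotypic correlation can fall outside
[-1, 1]; such cells are clamped for downstream use and flagged.

Significance uses the t approximation t = r * sqrt(g - 2) / sqrt(1 - r^2)
with g - 2 degrees of freedom, applied to both levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TrialDesign
from .errors import LattiqError, SchemaError
from .simulate import PlotTable
from . import anova as _anova

__all__ = ["CorrMatrices", "covariance_components", "correlation_matrices"]


@dataclass(frozen=True)
class CorrMatrices:
    """Genotypic (rg) and phenotypic (rp) correlation matrices.

    ``sig_g`` / ``sig_p`` hold two-sided p-values per cell; ``overflow``
    marks cells whose raw genotypic correlation exceeded 1 in magnitude
    before clamping; ``undefined`` marks cells where a zero genotypic
    variance made rg undefined (stored as NaN).
    """

    traits: tuple[str, ...]
    rg: pd.DataFrame
    rp: pd.DataFrame
    sig_g: pd.DataFrame
    sig_p: pd.DataFrame
    overflow: pd.DataFrame
    undefined: pd.DataFrame
    df: int

    @classmethod
    def from_matrices(
        cls, rg: pd.DataFrame, rp: pd.DataFrame, n_genotypes: int
    ) -> "CorrMatrices":
        """Wrap already-estimated correlation matrices (e.g. published ones),
        attaching t-approximation p-values at ``n_genotypes - 2`` df."""
        traits = tuple(rg.index)
        df = n_genotypes - 2
        falsy = pd.DataFrame(
            np.zeros((len(traits),) * 2, dtype=bool), index=rg.index, columns=rg.columns
        )

        def _p(m):
            return pd.DataFrame(
                _corr_pvalues(m.to_numpy(dtype=float), df),
                index=m.index,
                columns=m.columns,
            )

        return cls(
            traits=traits,
            rg=rg.copy(),
            rp=rp.copy(),
            sig_g=_p(rg),
            sig_p=_p(rp),
            overflow=falsy,
            undefined=falsy.copy(),
            df=df,
        )

    def combined_table(self, alpha_levels=(0.05, 0.01)) -> pd.DataFrame:
        """Triangular display: phenotypic below, genotypic above the diagonal."""
        t = len(self.traits)
        out = pd.DataFrame("", index=self.traits, columns=self.traits)
        for i, ti in enumerate(self.traits):
            for j, tj in enumerate(self.traits):
                if i == j:
                    out.iloc[i, j] = "1"
                elif i < j:  # genotypic above
                    out.iloc[i, j] = _fmt_cell(
                        self.rg.iloc[i, j], self.sig_g.iloc[i, j], alpha_levels
                    )
                else:  # phenotypic below
                    out.iloc[i, j] = _fmt_cell(
                        self.rp.iloc[i, j], self.sig_p.iloc[i, j], alpha_levels
                    )
        return out


def _fmt_cell(r: float, p: float, alpha_levels) -> str:
    if not np.isfinite(r):
        return "NA"
    stars = ""
    if np.isfinite(p):
        if p <= alpha_levels[1]:
            stars = "**"
        elif p <= alpha_levels[0]:
            stars = "*"
    return f"{r:.2f}{stars}"


def covariance_components(
    plots: PlotTable,
    design: TrialDesign,
    traitX: str,
    traitY: str,
    qs=None,
) -> tuple[float, float, float]:
    """(cov_g, cov_e, cov_p) between two traits from lattice mean cross-products."""
    for t in (traitX, traitY):
        if t not in plots.traits:
            raise SchemaError(f"trait {t!r} not present in plot table")
    plots.check_balanced(design)
    if qs is None:
        order, qs = _anova.sequential_projectors(design)
    else:
        order = design.to_frame()
    x = plots.trait_vector(traitX, order)
    y = plots.trait_vector(traitY, order)
    cps = _anova.sequential_crossproducts(design, x, y, qs=qs)
    dfs = dict(zip(_anova.FIT_SOURCES, _anova._dfs(design, qs)))
    mcp_acc = cps["accession"] / dfs["accession"]
    mcp_res = cps["residual"] / dfs["residual"]
    k, r = design.k, design.r
    cov_g = (k + 1) * (mcp_acc - mcp_res) / (k * r)
    cov_e = mcp_res
    return float(cov_g), float(cov_e), float(cov_g + cov_e)


def correlation_matrices(
    plots: PlotTable, design: TrialDesign, traits: list[str] | None = None
) -> CorrMatrices:
    """All pairwise genotypic and phenotypic correlations with p-values."""
    traits = tuple(traits or plots.traits)
    if len(traits) < 2:
        raise LattiqError("need at least two traits for a correlation matrix")
    g = design.g
    if g < 3:
        raise LattiqError(f"need at least 3 genotypes for correlation tests, got {g}")
    plots.check_balanced(design)
    order, qs = _anova.sequential_projectors(design)
    dfs = dict(zip(_anova.FIT_SOURCES, _anova._dfs(design, qs)))
    k, r = design.k, design.r

    vectors = {t: plots.trait_vector(t, order) for t in traits}
    nt = len(traits)
    # raw genotypic/residual MCP for every pair in one pass
    mcp_acc = np.zeros((nt, nt))
    mcp_res = np.zeros((nt, nt))
    for i, ti in enumerate(traits):
        for j in range(i, nt):
            cps = _anova.sequential_crossproducts(
                design, vectors[ti], vectors[traits[j]], qs=qs
            )
            mcp_acc[i, j] = mcp_acc[j, i] = cps["accession"] / dfs["accession"]
            mcp_res[i, j] = mcp_res[j, i] = cps["residual"] / dfs["residual"]

    cov_g_raw = (k + 1) * (mcp_acc - mcp_res) / (k * r)
    # diagonal variances follow the truncation rule of the univariate route
    s2g = np.maximum(np.diag(cov_g_raw), 0.0)
    s2e = np.diag(mcp_res)
    s2p = s2g + s2e
    cov_p = cov_g_raw + mcp_res

    rg = np.full((nt, nt), np.nan)
    rp = np.full((nt, nt), np.nan)
    overflow = np.zeros((nt, nt), dtype=bool)
    undefined = np.zeros((nt, nt), dtype=bool)
    for i in range(nt):
        for j in range(nt):
            if i == j:
                rg[i, j] = 1.0 if s2g[i] > 0 else np.nan
                undefined[i, j] = s2g[i] <= 0
                rp[i, j] = 1.0
                continue
            if s2g[i] > 0 and s2g[j] > 0:
                raw = cov_g_raw[i, j] / np.sqrt(s2g[i] * s2g[j])
                overflow[i, j] = abs(raw) > 1
                rg[i, j] = np.clip(raw, -1.0, 1.0)
            else:
                undefined[i, j] = True
            rp[i, j] = np.clip(
                cov_p[i, j] / np.sqrt(s2p[i] * s2p[j]), -1.0, 1.0
            )

    df = g - 2
    sig_g = _corr_pvalues(rg, df)
    sig_p = _corr_pvalues(rp, df)

    def _frame(a):
        return pd.DataFrame(a, index=list(traits), columns=list(traits))

    return CorrMatrices(
        traits=traits,
        rg=_frame(rg),
        rp=_frame(rp),
        sig_g=_frame(sig_g),
        sig_p=_frame(sig_p),
        overflow=_frame(overflow),
        undefined=_frame(undefined),
        df=df,
    )


def _corr_pvalues(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p-values for correlations via the t transform."""
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
        p = 2.0 * stats.t.sf(np.abs(tval), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isfinite(r), p, np.nan)
    np.fill_diagonal(p, np.nan)
    return p
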