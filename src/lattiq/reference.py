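"""Published summary statistics from a 49-accession barley landrace trial.

The package's worked examples reproduce the derived quantities of a
morpho-agronomic variability study of 49 Ethiopian barley (Hordeum
vulgare L.) landrace accessions grown in a 7 x 7 simple lattice with two
replications (Holetta, 2021 main season).  The raw plot data of that
trial are not public, but its summary tables are, and every derived
statistic in this package can be checked against them: variance
components from the printed mean squares, heritability and genetic
advance from the printed components, path coefficients from the printed
correlations.

Traits (11): DTH days to heading (d), DTM days to maturity (d), PLHT
plant height (cm), PDL peduncle length (cm), NFT fertile tillers, SL
spike length (cm), NSPS spikelets per spike, NKPS kernels per spike,
WKPS kernel weight per spike (g), TKW thousand-kernel weight (g), GY
grain yield (t/ha).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAITS = (
    "DTH", "DTM", "PLHT", "PDL", "NFT", "SL",
    "NSPS", "NKPS", "WKPS", "TKW", "GY",
)

K, R, G = 7, 2, 49  # block size, replications, accessions

# Intra-block ANOVA mean squares per trait (sources x traits), and the
# plot-level CV% row, as published.
ANOVA_MS = pd.DataFrame(
    {
        "DTH": [32.0, 93.6, 10.56, 4.15],
        "DTM": [34.33, 114.68, 69.90, 5.5],
        "PLHT": [530.17, 205.26, 98.83, 13.95],
        "PDL": [0.83, 12.3, 2.47, 1.9],
        "NFT": [0.18, 0.48, 0.19, 0.21],
        "SL": [1.56, 1.73, 0.78, 0.25],
        "NSPS": [11.55, 7.68, 1.48, 1.2],
        "NKPS": [48.84, 165.93, 28.64, 19.72],
        "WKPS": [0.93, 0.58, 0.09, 0.06],
        "TKW": [0.09, 59.91, 5.83, 4.93],
        "GY": [0.35, 2.03, 0.25, 0.16],
    },
    index=["replication", "accession", "block_within_rep", "residual"],
)

ANOVA_CV_PERCENT = pd.Series(
    [2.8, 2.1, 3.8, 3.7, 14.6, 6.4, 5.0, 10.8, 14.1, 5.9, 10.0], index=TRAITS
)

# Variability components per trait: mean, genotypic / phenotypic variance,
# GCV%, PCV%, broad-sense H2%, genetic advance and GA as % of mean.
VARIABILITY = pd.DataFrame(
    {
        "mean": [71.7, 113.7, 97.5, 36.9, 3.11, 7.87, 21.8, 41.2, 1.70, 37.4, 4.02],
        "sigma2_g": [51.12, 62.39, 109.3, 5.94, 0.16, 0.85, 3.70, 83.6, 0.30, 31.4, 1.07],
        "sigma2_p": [55.27, 67.89, 123.3, 7.84, 0.36, 1.10, 4.90, 103.3, 0.36, 36.35, 1.23],
        "gcv_percent": [9.97, 6.95, 10.7, 6.61, 12.7, 11.7, 8.84, 22.2, 32.3, 14.9, 25.7],
        "pcv_percent": [10.36, 7.25, 11.39, 7.59, 19.32, 13.31, 10.17, 24.65, 35.18, 16.13, 27.60],
        "h2_percent": [92.50, 91.90, 88.68, 75.75, 43.18, 76.81, 75.53, 80.90, 84.05, 86.45, 86.95],
        "ga": [14.19, 15.62, 20.31, 4.38, 0.54, 1.66, 3.45, 16.96, 1.04, 10.75, 1.99],
        "gam_percent": [19.78, 13.74, 20.84, 11.87, 17.21, 21.09, 15.85, 41.83, 60.99, 28.76, 49.51],
    },
    index=TRAITS,
)

# Pairwise trait correlations (2 dp as published): genotypic above the
# diagonal, phenotypic below, reassembled here into two full symmetric
# matrices.
_RG_UPPER = [
    # DTH    DTM   PLHT   PDL    NFT    SL    NSPS  NKPS   WKPS   TKW    GY
    [1.00, 0.72, 0.45, -0.07, 0.20, -0.37, 0.30, 0.56, 0.68, 0.09, 0.39],
    [0.00, 1.00, 0.43, -0.23, 0.27, -0.18, 0.42, 0.54, 0.69, 0.26, 0.51],
    [0.00, 0.00, 1.00, 0.46, 0.23, -0.09, 0.45, 0.47, 0.56, 0.39, 0.40],
    [0.00, 0.00, 0.00, 1.00, 0.17, 0.30, 0.16, 0.07, -0.06, 0.34, 0.12],
    [0.00, 0.00, 0.00, 0.00, 1.00, -0.06, 0.77, 0.56, 0.27, 0.72, 0.85],
    [0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.13, -0.40, -0.46, 0.19, -0.11],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.62, 0.47, 0.79, 0.87],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.81, 0.45, 0.73],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.27, 0.51],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.81],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00],
]

_RP_LOWER = [
    [1.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.69, 1.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.38, 0.31, 1.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [-0.07, -0.18, 0.42, 1.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.19, 0.29, 0.16, 0.16, 1.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [-0.30, -0.09, -0.13, 0.30, -0.02, 1.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.29, 0.41, 0.42, 0.18, 0.63, 0.12, 1.00, 0.00, 0.00, 0.00, 0.00],
    [0.51, 0.48, 0.43, 0.06, 0.44, -0.31, 0.57, 1.00, 0.00, 0.00, 0.00],
    [0.64, 0.63, 0.52, -0.05, 0.25, -0.35, 0.46, 0.76, 1.00, 0.00, 0.00],
    [0.06, 0.24, 0.34, 0.31, 0.61, 0.16, 0.70, 0.43, 0.26, 1.00, 0.00],
    [0.36, 0.47, 0.33, 0.11, 0.72, -0.09, 0.78, 0.69, 0.46, 0.77, 1.00],
]


def _symmetrize(m: list, upper: bool) -> pd.DataFrame:
    a = np.array(m)
    out = np.triu(a, 1) + np.triu(a, 1).T if upper else np.tril(a, -1) + np.tril(a, -1).T
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=TRAITS, columns=TRAITS)


GENOTYPIC_CORR = _symmetrize(_RG_UPPER, upper=True)
PHENOTYPIC_CORR = _symmetrize(_RP_LOWER, upper=False)

# Path analysis of grain yield on the 8 traits significantly correlated
# with it: full published effect matrices (direct effects on the diagonal,
# indirect effects off it) and the yield-correlation column.
PATH_PREDICTORS = ("DTH", "DTM", "PLHT", "NFT", "NSPS", "NKPS", "WKPS", "TKW")

PATH_GENOTYPIC = pd.DataFrame(
    [
        [0.094, 0.098, -0.025, 0.055, 0.068, 0.180, -0.101, 0.028],
        [0.068, 0.136, -0.024, 0.073, 0.095, 0.174, -0.101, 0.085],
        [0.042, 0.059, -0.055, 0.062, 0.102, 0.153, -0.082, 0.122],
        [0.019, 0.037, -0.013, 0.271, 0.173, 0.182, -0.041, 0.221],
        [0.028, 0.058, -0.025, 0.208, 0.225, 0.200, -0.069, 0.246],
        [0.052, 0.073, -0.026, 0.152, 0.139, 0.324, -0.120, 0.138],
        [0.064, 0.094, -0.031, 0.075, 0.106, 0.263, -0.147, 0.084],
        [0.008, 0.038, -0.022, 0.195, 0.179, 0.145, -0.040, 0.308],
    ],
    index=PATH_PREDICTORS,
    columns=PATH_PREDICTORS,
)
PATH_GENOTYPIC_RY = pd.Series(
    [0.397, 0.505, 0.402, 0.849, 0.870, 0.733, 0.507, 0.811],
    index=PATH_PREDICTORS,
)
PATH_GENOTYPIC_RESIDUAL = 0.077

PATH_PHENOTYPIC = pd.DataFrame(
    [
        [0.112, 0.071, -0.029, 0.031, 0.069, 0.182, -0.101, 0.025],
        [0.077, 0.103, -0.023, 0.048, 0.095, 0.171, -0.099, 0.092],
        [0.042, 0.032, -0.075, 0.026, 0.097, 0.154, -0.081, 0.132],
        [0.021, 0.030, -0.012, 0.167, 0.146, 0.168, -0.039, 0.235],
        [0.033, 0.042, -0.031, 0.105, 0.233, 0.202, -0.072, 0.273],
        [0.056, 0.050, -0.033, 0.079, 0.133, 0.355, -0.119, 0.167],
        [0.072, 0.065, -0.039, 0.042, 0.107, 0.268, -0.157, 0.100],
        [0.007, 0.024, -0.026, 0.101, 0.164, 0.152, -0.040, 0.388],
    ],
    index=PATH_PREDICTORS,
    columns=PATH_PREDICTORS,
)
PATH_PHENOTYPIC_RY = pd.Series(
    [0.360, 0.464, 0.326, 0.716, 0.784, 0.689, 0.457, 0.771],
    index=PATH_PREDICTORS,
)
PATH_PHENOTYPIC_RESIDUAL = 0.1623

# Correlation-matrix PCA: eigenvalues of the three retained components
# (Kaiser criterion) and their percent variance explained.
PCA_EIGENVALUES = pd.Series([5.26, 2.26, 1.25], index=["PC1", "PC2", "PC3"])
PCA_VAR_EXPLAINED = pd.Series([47.79, 20.54, 11.33], index=["PC1", "PC2", "PC3"])

# Overall genetic-distance summary on standardized traits.
DISTANCE_OVERALL = {"min": 1.07, "max": 9.24, "mean": 4.44, "sd": 1.5, "cv_percent": 33.8}


def reference_genetic_model(
    traits=("DTH",), rg: np.ndarray | None = None, sigma2_b: float = 3.0
):
    """A :class:`~lattiq.simulate.GeneticModel` at the published trial's scale.

    Grand means and genotypic / environmental variances are taken from
    the published variability components for the requested traits; the
    genetic correlation matrix defaults to the published genotypic
    correlations of those traits.  Block variance is not derivable from
    the published tables and defaults to a magnitude comparable to the
    residual variances (3.0, trait units squared).
    """
    from .simulate import GeneticModel

    traits = tuple(traits)
    t = len(traits)
    if rg is None:
        rg = GENOTYPIC_CORR.loc[list(traits), list(traits)].to_numpy()
        # nudge to the nearest PSD matrix if the published rounding broke it
        w, v = np.linalg.eigh(rg)
        if w.min() < 0:
            rg = v @ np.diag(np.maximum(w, 1e-8)) @ v.T
            d = np.sqrt(np.diag(rg))
            rg = rg / np.outer(d, d)
            rg = (rg + rg.T) / 2
            np.fill_diagonal(rg, 1.0)
    return GeneticModel(
        trait_names=traits,
        mu=VARIABILITY.loc[list(traits), "mean"].to_numpy(),
        sigma2_g=VARIABILITY.loc[list(traits), "sigma2_g"].to_numpy(),
        Rg=np.asarray(rg, float),
        sigma2_b=np.full(t, sigma2_b),
        sigma2_e=ANOVA_MS.loc["residual", list(traits)].to_numpy(),
        Re=np.eye(t),
        rep_effects=np.zeros((2, t)),
    )
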