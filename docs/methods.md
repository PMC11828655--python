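# Methods

## The trial model

The package analyses plot observations from a simple (square) lattice:
`g = k²` genotypes, `r = 2` replications, each replication resolved into
`k` incomplete blocks of `k` plots (rows and columns of the k×k square,
so two genotypes meet in at most one block). The working model for a plot
value of trait *v* is

    y = mu_v + rep_j,v + block(j,b),v + G_a,v + e

with fixed replication shifts, random block effects (variance `σ²b`),
random genotype effects (variance `σ²g`) and plot error (variance `σ²e`).
Across traits the genotype effects follow a multivariate normal with
correlation matrix `Rg`, and the errors one with `Re`; block effects are
drawn independently per trait. All estimators in the package are
moment-based, so normality matters only for p-values, not for the
component estimates themselves.

## Intra-block ANOVA and the choice of adjustment

The per-trait partition is sequential (type-I), computed by projecting
onto nested model spaces (orthonormal bases via SVD):
replication → block-within-replication (unadjusted) → **accession
adjusted for blocks** → intra-block residual, with degrees of freedom
1, 2(k−1), k²−1 and n−k²−2k+1 (1, 12, 48, 36 at k=7). Tables are
displayed with accessions before blocks, the conventional layout.

Fitting accessions *after* blocks is a deliberate and load-bearing
choice. Under the random-block model the block-adjusted accession mean
square has expectation

    E[Msg] = σ²e + (k·r/(k+1))·σ²g

so the moment estimator `σ̂²g = (k+1)(Msg − Mse)/(k·r)` is exactly
unbiased — the `k·r/(k+1)` factor is the effective replication of
intra-block-adjusted genotype comparisons. The alternative (accessions
unadjusted, blocks eliminating accessions) inflates the estimator by the
factor (k+1)/k plus block leakage — about +14% at k=7 even with no block
variance — which simulation confirms. The reference trial's published
accession mean squares are consistent with the adjusted expectation at
the published component values, supporting this reading.

F-tests use the intra-block residual; no inter-block information is
recovered (no REML). Negative `σ̂²g` (possible when `Msg < Mse`) is
truncated to zero and flagged, since GCV and GA need its square root.

Adjusted accession means come from the full fixed-effects least-squares
fit with sum-to-zero coding; because every non-intercept column sums to
zero over plots, the intercept equals the plot grand mean exactly, and
the mean of adjusted means equals the grand mean. The reported SEM of an
accession mean is the root of `Mse` times the average prediction-variance
coefficient of the `intercept + effect` functionals.

Tukey mean separation uses `HSD = q(1−α; g, df_e)·sqrt(Mse/r)` with `r`
as the common replicate count; the slight effective-error inflation of
lattice-adjusted comparisons is deliberately omitted (its size depends on
the block-variance weighting the intra-block analysis does not estimate).
Letters are assigned by a greedy maximal-window sweep over the descending
means, which for a common SEM reproduces the all-pairs comparison
exactly.

## Covariances, correlations, path analysis

Cross-products between two traits reuse the ANOVA's projectors
bilinearly (`CP_s = x'P_s y`), so covariance components satisfy the
polarization identity by construction and the diagonal reproduces the
univariate variance components. Genotypic correlations are
`cov_g/sqrt(σ²g_x σ²g_y)`; being ratios of moment estimates they can
exceed 1 in magnitude, in which case they are clamped for downstream use
and flagged. Significance for both genotypic and phenotypic correlations
uses the t transform `t = r·sqrt(g−2)/sqrt(1−r²)` with `g−2` df — for
the genotypic level this is an approximation (the exact sampling
distribution depends on all components) and is documented as such.

Path coefficients solve `Rxx·P = rxy` by a dense linear solve; the
row-sum identity `direct + Σ indirect = r` then holds to machine
precision. A condition number above 1e3 raises a warning, above 1e12 an
error naming the most collinear pair. The residual is reported primarily
as `1 − ΣP_i·r_iy` (the unexplained share of yield variation, matching
the convention of the reference study) with the classical square-root
residual path alongside. When the inputs are independently rounded
correlations this quantity can go slightly negative; it is reported with
a warning, never clamped. Predictor screening keeps traits significantly
correlated with yield at the chosen level and α, in input order.

## Diversity and PCA

Accession-by-trait mean matrices are z-scored per trait with the sample
(n−1) standard deviation; distances are plain Euclidean on the z-rows.
UPGMA is implemented directly (size-weighted Lance–Williams update) with
deterministic lexicographic tie-breaking on the smallest member indices,
so dendrograms are reproducible across platforms; the test suite checks
it against both a naive O(n³) re-scan oracle and scipy's average-linkage
on tie-free inputs. Dendrogram heights are the raw merge distances;
newick branch lengths are half the height differences, making
leaf-to-root depths half the final merge height. Cluster labels are
numbered by each cluster's first accession. The number of clusters K is
a required input — the package deliberately offers no automatic-K
statistic. Clustering operates on adjusted means for consistency with
the ANOVA.

PCA eigendecomposes the trait correlation matrix of the same z-scored
data (`eigh`); eigenvalues sum to the trait count, loadings are
orthonormal, scores are `Z·loadings` (variance equal to the eigenvalue,
ddof=1). Eigenvector sign is fixed by making each column's
largest-magnitude entry positive. Kaiser retention keeps eigenvalues
above 1. With fewer accessions than traits the trailing eigenvalues are
zeroed and a rank warning raised.

## The simulator and what recovery tests show

`simulate_trial` draws, in fixed order from a single seeded generator,
genotype effect rows (multivariate normal, SVD factorization), one block
effect per (replication, block, trait), and plot errors. Identical
(design, model, seed) gives a byte-identical CSV. Defaults in
`lattiq.reference.reference_genetic_model` place grand means, `σ²g` and
`σ²e` at the published per-trait values of the reference trial and `Rg`
at its published genotypic correlations; the block variance, not
derivable from published summaries, defaults to 3.0 (same order as the
residual variances of the phenology traits). Recovery tests at this
scale (200 trials) recover `σ²g` with median error ~1%, heritability
within a fraction of a point, and planted genetic correlations within
0.05.

The generator emulates exactly the additive variance-component structure
the estimators assume: no genotype×environment interaction, no spatial
trend, no trait-correlated block effects, normal errors, complete
balanced data. Passing recovery tests therefore demonstrate estimator
correctness under the model, not robustness of the model itself to field
realities (missing plots, spatial autocorrelation, non-normal traits).

## Numerical conventions and problem sizes

- Projector ranks (hence df) come from SVD with default tolerances;
  SS additivity is tested to 1e-8 relative.
- Category thresholds: GCV/PCV low <10, moderate 10–20, high >20;
  H² low <30, moderate 30–60, high >60; GAM low <10, moderate 10–20,
  high >20 — configurable via `CategoryThresholds`.
- `k_sel` defaults to 2.063 (standardized selection differential at 5%
  intensity) and is a distinct symbol from the block size.
- Path-effect magnitude classes: negligible ≤0.095, low ≤0.195, moderate
  ≤0.295, high ≤1.0, very high above (boundaries placed at half-ulp of
  3-dp effect tables).
- Monte-Carlo test sizes are 60–200 trials of the 98-plot lattice, enough
  to pin medians/means at the tolerances tested while keeping the full
  suite around ten seconds.

## Known limitations

- No recovery of inter-block information and no REML/mixed-model path;
  the intra-block analysis is the package's scope.
- No missing-plot imputation: analyses require complete balanced tables
  and fail loudly otherwise.
- Genotypic-correlation significance is approximate (see above).
- Standard errors for variance components, genotypic correlations and
  path coefficients are not provided.
- Only square lattices with two replications are supported (no
  rectangular or α-designs, no >2 replications).
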