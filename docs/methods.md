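# Methods

## Model and procedure

The package treats spatial co-expression as a conditional-correlation
problem. Per-cell expression `Y` (cells x genes) and per-cell confounders
`X` (cells x confounders) are aggregated over each cell's spatial
neighborhood `N(i)` into environment matrices `Y^(N)` and `X^(N)`
(neighbor *sums*, per the defining formula; a mean option exists — for a
fixed-k KNN graph the two differ only by a constant factor that cancels in
any correlation, while for radius graphs they differ materially, which is
why the sum is the default). The statistic of interest is

    cor(Y^(N) | X^(N))

computed from the Schur-complement conditional covariance

    cov(Y^N) - cov(Y^N, X^N) cov(X^N)^+ cov(X^N, Y^N)

rescaled to unit diagonal. This is algebraically identical to the
covariance of residuals after ordinary least squares of `Y^(N)` on
`X^(N)` with an intercept; both `Y` and `X` columns are mean-centered
before the computation, which makes the question of whether `X` is
centered moot. The formula is exact for multivariate normal data; since
each environment value is a sum over ~50 cells, the central limit theorem
makes the normal approximation reasonable. The implementation treats the
Schur complement as the *definition*, valid regardless of distribution.

**Confounders.** Cell type enters as one indicator column per level;
categorical technical covariates (sample/FOV id) likewise; numeric
covariates (per-cell total counts, negative-control-probe counts) enter
as-is. All are then neighbor-summed, so the conditioning is on
*neighborhood* composition and *neighborhood* technical load, not on the
single cell's own values. With a fixed-k graph a neighbor-summed numeric
covariate equals k+1 times the neighborhood mean, so "mean neighborhood
total counts" is conditioned on up to an absorbed constant.

**Rank deficiency and numerical tolerances.** One-hot blocks are exactly
collinear after centering (type counts sum to the neighborhood size), so
`cov(X^N)` is singular by construction. The pseudo-inverse truncates
singular values below `1e-10` relative to the largest; this cutoff sits
far above float-64 noise and far below any genuine signal, and makes the
result invariant (to ~1e-6) to adding exact linear combinations of
existing columns. Genes whose conditional variance falls below `1e-12`
of the mean conditional variance are flagged zero-variance and get zero
rows/columns rather than NaNs. Conditional correlations are clipped to
[-1, 1] and symmetrized (the asymmetry being float noise at ~1e-16).

**Subsampling.** The covariance is estimated on a uniform random
subsample of cells (default `max_cells = 5000`), drawn without
replacement with a seeded generator and sorted. The same subsample is
reused for the raw matrix `cor(Y^(N))` within a run, so raw-vs-conditional
comparisons are paired, and by default for attribution as well.

**Modules.** The conditional correlation matrix is sparsified by zeroing
entries *below* the edge threshold (default 0.2; the boundary value is
kept). Negative correlations are therefore removed: anti-correlated
pairs cannot join a module — a documented limitation, matching the
method's intent of finding mutually co-expressed sets. Leiden community
detection (igraph/leidenalg, RB-configuration objective, resolution 1.0,
fixed seed, 2 iterations) partitions the weighted graph; communities
larger than `max_module_size` (20) are re-partitioned exactly once at
double resolution; communities smaller than `min_module_size` (3) or with
mean pairwise conditional correlation below `min_avg_cor` (0.1) are
discarded; isolated genes never form modules. The resolution and
objective are declared defaults, not canonical values. Modules are named
by their two most influential genes, influence being the gene's weighted
degree within the module on the thresholded graph (ties alphabetical,
name collisions suffixed `_2`, `_3`, ...). "Influence" had to be made
concrete somewhere; weighted within-module degree is the adopted
criterion.

**Scores and attribution.** Module scores are weighted sums
`M_im = sum_j w_j Y_ij` (single-cell) and `M^N_im = sum_j w_j Y^N_ij`
(environment) with inverse-square-root weights
`w_j = mean(Y^N_.j)^-0.5`, damping the Poisson mean-variance relation so
abundant genes do not dominate. The weighted *sum* formula is taken
literally; an option renormalizes weights to sum to one (scale change
only). Attribution computes `A(j,c)`, the Pearson correlation between a
module's environment score and the neighborhood expression of gene j
contributed by type-c cells alone (`Y^(N,c)`), and summarizes
`A(c) = max_j A(j,c)`. The per-type environment matrices partition the
total exactly: `sum_c Y^(N,c) = Y^(N)`. Attribution uses normalized
expression, consistent with the correlation stage.

**Neighborhoods.** KNN (default k = 50) with exact Euclidean distances
and ties broken toward the lower cell index for determinism; fixed
radius (default 0.05 length units, suited to TMA-core-scale data); or
custom neighbor lists (accepted verbatim, no symmetrization, duplicates
dropped with a warning). `include_self` defaults to true — a cell is part
of its own environment; the flag is exposed because either convention is
defensible. Distances are 2-D Euclidean; z-stacks and barrier-aware
neighborhoods are out of scope.

**Preprocessing.** Optional per-cell filter keeping cells with total raw
counts >= `min_counts` (a filter described as removing cells *below* 20
keeps 20 itself); default off except in radius-graph TMA-style recipes.
Normalization divides each cell's profile by its total counts, giving
proportions; no depth-median rescaling constant is applied because any
constant cancels in correlations. Filtering must precede normalization:
zero-total cells are a hard error directing to the filter, and the count
filter itself refuses to run on already-normalized data.

**Multi-sample runs.** Each sample gets its own neighborhood graph and
subsample, with per-sample seed = master seed + sample index. Samples
with fewer than `min_cells_per_sample` (3000) cells are skipped with a
warning. Genes are aligned by intersection across retained samples
(union-with-zeros was rejected: the correlation of an absent gene is
undefined, not zero). Consensus pairs exceed a correlation threshold
(default 0.3) in at least `ceil(17/19 * n)` samples; variable pairs
exceed `hi` (default 0.3) in >= 3 samples and fall below `lo` (0.05) in
>= 3. The `hi` default follows the analysis recipe rather than the
alternative 0.4 mentioned in narrative summaries of the same analysis;
it is a parameter either way.

## Synthetic data generator

The generator emulates the data-generating structure the method assumes:

* **Spatially organized cell types** — each type concentrates around a
  few Gaussian niches (default 4 niches, sd 0.08 in a 1 x 1 arena) with a
  10% uniformly mixed fraction, so neighborhood composition varies
  smoothly and induces the marker-correlation confound the method is
  built to remove.
* **Markers** — 10 genes per type at Poisson rate 1.0 in the home type
  and 0.02 elsewhere.
* **Planted programs** — disjoint 6-gene sets whose rates are multiplied
  by `1 + amplitude * field(x, y)` where the latent field is a sum of 8
  isotropic Gaussian bumps (radius 0.12) clipped to [0, 1]; amplitude
  defaults to 3. Programs can be restricted to chosen cell types.
  Fields are independent across programs; bump geometry keeps them small
  enough that chance overlap rarely produces cross-program correlation
  above the module threshold.
* **Technical structure** — per-cell log-normal depth factors
  (sigma 0.35, mean normalized to 1), a flat background rate (0.01), a
  simulated negative-probe total (rate 0.5 x depth), a grid of FOV ids,
  and an optional per-FOV multiplicative artifact for QC workflows.
  Counts are Poisson with an optional gamma overdispersion knob.
* **Panel composition** — 100 unstructured filler genes at rate 0.5, so
  a cell's expected total is ~60-70 counts and any single program is a
  few percent of the transcriptome. This matters: with a tiny panel, a
  boosted program meaningfully dilutes every other gene's proportion
  after total-count normalization, creating compositional correlations
  that real panels (hundreds to thousands of genes) do not exhibit at
  that magnitude. Program amplitudes and panel composition were fixed by
  pilot calibration and frozen with the seeds used in the test suite.

What the generator does **not** emulate: segmentation errors, optical
crowding, cell-shape effects, FOV-edge artifacts (beyond the explicit
artifact flag), negative binomial bursts (unless the overdispersion knob
is turned), or 3-D structure. Passing tests therefore demonstrate the
statistical machinery — confounder removal, program recovery, stability,
determinism — on data that obeys the model's assumptions; they do not
certify behavior under those real-data pathologies, where the method is
known to surface technical artifacts as (easily recognized) modules.

## Study sizes used in tests and the acceptance script

Marker-deflation and program-recovery studies use 10,000 cells (3 types,
30 markers, 3 planted programs of 6 genes, ~160-gene panel); subsample
stability uses 20,000 cells; multi-sample consensus uses 4 tissues of
4,000 cells sharing one planted program. These sizes give stable medians
and recovery metrics while keeping a full run in seconds.

## Known limitations

* Anti-correlated gene pairs are invisible to module detection (positive
  threshold).
* Conditioning is linear; nonlinear dependence on confounders (e.g. the
  residual compositional coupling of proportions) is only partially
  removed, and shows up as small same-type marker correlations (|r| well
  under the 0.2 module threshold in the simulated studies).
* Neighborhoods are geometric proxies; real signaling reach varies by
  gene and is blocked by tissue structure, attenuating true conditional
  correlations.
* No significance testing, by design: effect-size thresholds replace
  p-values at these sample sizes.
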