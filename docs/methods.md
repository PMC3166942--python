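# Methods

## The collapsing problem

Given a numeric matrix whose rows are variables (probes, genes, markers) and
whose columns are observations, plus a mapping from rows to groups, produce a
matrix with one row per group. Two families of methods are implemented:

- *representatives* select one existing row per group, so the output row is a
  bit-identical copy of an input row and carries its identity in the result's
  provenance table;
- *composites* synthesize a new row (the column-wise average, the first
  principal component, or a user-supplied aggregator).

### Dispatch and pre-processing

1. Rows without a usable group label are dropped (logged count). Rows whose
   values are entirely missing are dropped at validation, since no method can
   score them.
2. With `select_fewest_missing` (default on), each group is trimmed to the
   rows attaining the group's minimum missing-value count. The trim precedes
   everything else, including the connectivity dispatch: whether a group uses
   network selection is decided by its *trimmed* size. A group never
   vanishes, because its minimum is always attained.
3. Composite methods aggregate every group regardless of the
   connectivity-based flag. Representative methods dispatch per group:
   singletons pass through; with connectivity-based collapsing, groups of
   three or more rows take the network hub and two-row groups fall back to
   the configured biostatistical method (correlation networks are not
   meaningful below three variables); otherwise the scored representative is
   taken.

### Scores and tie rules

`MaxMean` / `MinMean` score rows by the mean over non-missing entries,
`absMaxMean` / `absMinMean` by the mean absolute value, `maxRowVariance` by
the unbiased (n−1) sample variance. The unbiased variance is a convention
choice: after missingness the per-row counts can differ, so the denominator
matters and must be fixed; we document and test (n−1). A row with fewer than
two observed values has no variance; it loses every comparison.

Score ties are broken by the highest sample mean; remaining ties uniformly at
random from a recorded seed, so "random" stays reproducible in a pipeline.
Connectivity ties take the first tied row in input order. These are the only
two places where input row order or the seed can influence the result; this
is verified by a permutation-invariance test.

## Signed network and connectivity

The adjacency between rows i and j is `a_ij = ((1 + r_ij)/2) ** beta` with
`r_ij` the Pearson correlation on pairwise-complete samples (at least three
shared observations required — the minimum for a non-degenerate correlation).
This maps r = −1 to adjacency 0, r = +1 to 1, and r = 0 to `2^-beta`,
preserving the sign and continuity of the correlation rather than
hard-thresholding it. The default soft power is beta = 1: collapsed groups
are typically small, so there is little need to sharpen the correlation
contrast. Connectivity is `k_i = Σ_{j≠i} a_ij` (diagonal excluded), the
standard weighted-network degree; the hub is its arg-max.

`whole_network_connectivity` computes the same statistic for every row of a
full (collapsed) matrix, accumulating the correlation matrix in row blocks so
memory stays bounded at thousands of rows; rows with missing values or zero
variance are excluded there with a warning, since their network-wide
correlations are undefined.

### Module eigengene

The `ME` composite standardizes each group row (missing cells imputed with
the row mean, which standardizes to zero), takes the first right-singular
vector of the standardized rows, and returns it at unit norm. First principal
components have arbitrary sign, and downstream uses are correlation-based and
hence sign-sensitive, so the vector is oriented to correlate non-negatively
with the group's mean row (falling back to the standardized mean, then to the
first non-zero coordinate, for degenerate means). A group whose rows are all
constant has no principal direction; it yields a zero vector with a warning.

## Evaluation framework

Two independently collapsed datasets measuring the same system should agree
on which genes are highly expressed and which are hubs. For each unordered
dataset pair and each strategy, both datasets are collapsed, restricted to
their shared group labels in sorted order, and compared by (a) the Spearman
correlation of per-row means and (b) the Spearman correlation of
whole-network connectivities, each network rebuilt per dataset after
collapsing with the same beta. Spearman with average ranks is used because
the comparison is defined on *ranked* summaries. Per strategy the framework
reports the mean of each correlation across pairs, its standard error
(sample SD / √pairs), and the fraction of pairs on which the strategy attains
the top correlation; exact ties split the win equally so the total is
conserved. An optional `none` baseline evaluates uncollapsed matrices
intersected on row identifiers directly.

## Deconvolution

Markers are ranked per cell type by fold change: (mean over the type's pure
columns + ε) / (mean over all other types' pure columns pooled + ε), with
ε = 1 on linear-scale intensities to guard zero denominators (log-scale input
should be linearized first). Pooling the non-target types is the simplest
denominator consistent with "enriched against the rest"; a gene qualifying
for several types is assigned only to its best type so that the marker→type
map is a valid group map (one group per row). Types with fewer than the
requested number of genes at fold change > 1 yield truncated, warned panels.

Prediction collapses the marker rows of the mixture matrix grouped by cell
type under any strategy, then divides each cell type's row by its sum across
samples. This scaling absorbs the unknown per-type constant — the method
recovers relative abundance only up to an affine transformation, like
converting between temperature scales — so accuracy is scored by Pearson
correlation against truth (rescaled by the same convention), pooled over all
(type, sample) points and per type. Eigengene-based predictions can be
negative; they are scaled by their signed sum and flagged rather than
rejected. For non-composite methods a non-positive collapsed row sum is an
error naming the type, because scaling by it would flip signs silently.

## Enrichment

For a user list of size K and reference list of size M in a universe of N
genes sharing k, the p-value is the hypergeometric upper tail P(X ≥ k)
(scipy's survival function; k = 0 returns exactly 1). The universe is a
required, logged parameter, and correction is Bonferroni across all tested
pairs (α = 0.05 default) — conservative and configurable; both are surfaced
explicitly because p-values are meaningless with a silent background. Symbols
are uppercased and trimmed before matching.

## Synthetic data

The generators produce the statistical structure each analysis assumes, with
Gaussian latent signals and noise throughout, bit-reproducible from the seed,
and a manifest carrying the planted truth.

**Probe→gene pairs.** Each gene receives a unit-variance latent per-sample
signal built from three latent factors whose loadings are shared between the
two datasets (factor scores are drawn fresh per dataset), so gene–gene
correlations — and hence connectivity rankings — reproduce across datasets
while the samples themselves are independent. Each probe reads its gene's
latent signal at its own signal fraction plus independent Gaussian noise
(defaults: 50 genes, 1–4 probes each, 20 samples, non-carrier fraction 0.5,
noise SD 1). One probe per gene is planted as the carrier with the highest
signal fraction (0.9) and the highest baseline offset, so max-mean selection
should find it. Under this design the expected correlation between two
probes at fraction f is f²/(f² + σ²), which is verified by a Monte-Carlo
test.

**Modules.** Each module is driven by a latent eigengene; member rows are
baseline + loading × eigengene + noise. Defaults place the planted hub at
loading 1.0 against members at 0.3–0.55 with noise SD 0.3 over 40 samples and
12 rows — a regime where the hub's connectivity advantage is clearly
identifiable against correlation sampling error, which is what "low noise"
must mean for hub recovery to be a meaningful check: with narrower loading
gaps, smaller modules or fewer samples, the sampling error of Pearson
correlations (order 1/√n) swamps the hub's margin and no selection rule could
recover it reliably.

**Mixtures.** Pure signatures give each marker gene a planted fold enrichment
(default 8×) over its base expression (uniform 20–100); four pre-specified
mixing designs in triplicate (12 samples) form the mixtures as signature ×
proportion products. Measurement noise is multiplicative with a per-gene
noise multiplier drawn uniformly from 0.5–2 independent of expression level;
values are clamped at zero to emulate intensity data (documented because the
clamp slightly biases fold changes). The independence of reliability and
expression level is the feature that separates strategies under noise: the
network hub of a marker group is its most *reliable* abundance proxy, while
max-mean selection is blind to reliability — mirroring the observed ranking
in which hub-based collapsing gives the most accurate predictions. Noise-free
mixtures are exactly affine in the true proportions, so per-type correlations
of 1.0 are an algebraic identity that the tests check to 1e−9.

What the generators do *not* emulate: platform-specific probe behaviour,
batch effects, heavy-tailed intensity distributions, correlated missingness,
or cross-platform probe annotation mismatches. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms under
their stated assumptions, not performance on any particular real dataset.

## Numerical and scale choices

- Correlations are clipped into [−1, 1] before the adjacency transform to
  absorb floating-point overshoot; the analytic endpoint identities
  (adjacency exactly 0 at r = −1 and 1 at r = +1, beta = 1) then hold
  exactly and are asserted as such.
- Monte-Carlo checks are sized to run on a laptop-class budget: 200 random
  matrices for oracle equivalence, 200 module replicates for hub recovery,
  50 mixture seeds for the noisy deconvolution comparison, 100 seeds for the
  null of the reproducibility metrics. These sizes give comfortable margins
  on every asserted bound at the chosen conditions.
- Output row order is always sorted group order; nothing else depends on
  file order except the documented tie rules.

## Known limitations

- Connectivity-based collapsing requires every trimmed group row to have
  non-zero variance and at least three shared samples per pair; degenerate
  rows raise rather than being silently skipped, and callers must pre-filter.
- The deconvolution estimates are relative only; no unit-sum-per-sample
  (absolute composition) estimation is attempted, and no multivariate
  regression deconvolution is implemented.
- No probe reannotation, module *detection*, unsigned or hard-threshold
  networks, topological overlap, or alternative centralities — module and
  group assignments are always inputs.
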