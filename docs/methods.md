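# Methods

This document records the statistical model behind each stage, the default
parameters, the numerical choices that affect results, and known
limitations. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; no further empirical claims are made.

## Bloom segmentation

Daily fluorescence `F_t` is converted to log growth rates
`r_t = ln(F_t / F_{t-1})` (an error is raised on non-positive values). A
bloom **starts** on the first day of a run of at least `min_pos_start = 2`
consecutive positive rates such that some window of at least
`min_window = 5` consecutive days anchored at that day has a positive rate
sum. It **ends** on the day before the first run of `end_neg_run = 5`
consecutive negative rates; if the series ends first, the bloom is
truncated there and the truncation is logged. Zero rates count as
non-positive for the start rule and non-negative for the end rule. Blooms
separated by at most `max_gap_weeks = 2` weeks (14 days) are pooled into
one, and non-bloom periods are restitched around the pooled blooms. All
events (starts, ends, truncations, pooling) are recorded in the period
set's provenance string.

Because the first day has no growth rate, periods start on the second
fluorescence day.

## Correlation networks

For every unordered taxon pair in a period's weekly abundance matrix the
Spearman rank correlation (mid-ranks for ties, via scipy) is tested with a
two-sided Monte-Carlo permutation test: the second series is permuted
`n_permutations = 9999` times and the p-value uses the add-one estimator

    p = (1 + #{ |rho_perm| >= |rho_obs| }) / (n_permutations + 1),

so p lies in (0, 1] and is never exactly zero. A tolerance of 1e-12 on the
comparison guards against ties lost to floating-point rounding.
Edges with p < `alpha = 0.05` (raw, uncorrected) enter the networks; the
negative and positive networks partition the combined network's edge set.

Per-pair randomness comes from a child generator keyed by
`(master_seed, taxon_a, taxon_b)`, so each edge's p-value is independent
of the order in which pairs are evaluated and of which other taxa are
present.

**Node-set convention:** a network's nodes are the endpoints of its edges;
taxa with no significant correlation are not counted in N. The combined
network can therefore have more nodes than either signed network.
Columns constant within a period are dropped before testing (logged and
recorded on the network object).

Descriptors are computed from the node/edge counts alone:
`mean_degree = round(2E/N, 2)` and `%negative = round(100 * E_neg / E)`.
The acceptance suite verifies this arithmetic against a published
reference descriptor table: six of nine printed mean degrees are
reproduced exactly at 2-decimal rounding and all three printed
percent-negative values at integer rounding; the remaining three printed
mean degrees differ from `2E/N` by 0.01–0.02 (7.30 vs 7.29, 3.50 vs 3.49,
6.04 vs 6.06). Those discrepancies are documented, not targeted.

Autocorrelation diagnostics (statsmodels ACF, lags 1–5, flagging
`|acf| > 1.96/sqrt(n)`) are reported for periods with at least 8 samples;
the permutation test assumes exchangeable samples and the diagnostic makes
violations visible rather than correcting for them.

## Erdős–Rényi null model

Each empirical network (n non-isolated nodes, m edges) is compared with
`n_random_networks = 999` uniform G(n, m) draws. Sampling is by index
sampling without replacement over the C(n, 2) pair space with a
closed-form inverse mapping from linear index to (i, j) (floating-point
square-root inversion with explicit off-by-one corrections; round-trip
verified exhaustively in tests). For every unordered pair of node labels
(self-pairs included) the empirical edge count is compared with the order
statistics at ranks `ceil(0.025 R)` and `ceil(0.975 R)` of the sorted null
counts (ranks 25 and 975 for R = 999): strictly below the lower one is
*rare*, strictly above the upper one *dominant*, otherwise *neutral*.
Strict inequalities on discrete counts make the classification
conservative: the per-pair false-verdict rate is bounded above by 5% and
is typically lower. The acceptance band used when the empirical networks
are themselves ER draws is [0.01, 0.055], fixed a priori from this
reasoning. The null keeps node identity (hence labels) but not the degree
sequence — it is a pure ER model, not a configuration model.

By default the random graphs live on the empirical network's non-isolated
node set; a `nodes` argument widens the universe to all catalogued taxa
when desired.

## Size classes (PELT) and biomass dominance

Within each size-classed compartment (phytoplankton, naked ciliates,
tintinnids) taxa are ordered by ESD and changepoints are found with the
PELT dynamic program under the Gaussian change-in-mean cost
(within-segment SSE divided by a variance scale). Defaults:

- penalty `2 ln(n)` (BIC-like),
- minimum segment length 2,
- variance scale: the Rice difference-based estimator
  `mean(diff(v)^2) / 2`, falling back to the overall variance and then
  to 1 for constant series. The Rice estimator is robust to the mean
  shifts the search is looking for, and makes the segmentation invariant
  under rescaling the ESD axis. (A median-based scale over-segments
  step-like data; the overall variance is inflated by the shifts
  themselves and under-segments.)

Pruning uses the standard PELT inequality for subadditive costs, so the
result is identical to exhaustive optimal partitioning — asserted against
an independent O(n²) dynamic-programming oracle in both the unit and
acceptance tests. Class boundaries are midpoints between the ESDs
flanking each changepoint, rounded for labels like `<6`, `6-12`, `>25`;
labels are prefixed with the group name so identical ranges in different
groups stay distinct. An optional flag runs the search on log-ESDs.

Biovolume is the ESD-equivalent sphere, `(pi/6) * ESD^3`. Mean abundance
times biovolume gives mean biovolume per mL; within each size-classed
compartment, taxa are sorted by it descending and the shortest prefix
reaching `dominance_threshold = 0.90` of the compartment total is
selected (ties with the last selected taxon included; pass-through
compartments — viruses, bacteria, heterotrophic flagellates — are
selected whole; all-zero compartments select nothing, logged).

## Inter-annual comparison

Campaigns are paired by ISO-8601 week *number* (cross-year: a date in
late December can belong to week 1 of the next ISO year). Duplicate weeks
within a campaign are an error; by default the longer campaign's
unmatched trailing weeks are truncated, otherwise unmatched weeks raise.
Per functional group or size class, weekly summed abundances are compared
with the paired Wilcoxon signed-rank test (scipy): zero differences
discarded (Wilcoxon's original treatment, not Pratt's), exact p for up to
25 tie-free nonzero differences, normal approximation with continuity and
tie correction above. W is the smaller signed-rank sum. Exactness is
verified against full 2^n sign enumeration in tests. No correction across
the multiple per-group tests is applied; p-values are reported raw.

## Synthetic generator

Abundances are drawn from a latent Gaussian copula: a multivariate normal
with 1s on the diagonal and planted pair correlations (attenuated by
`1/(1 + noise_sd^2)` when observation noise is requested), pushed through
strictly increasing lognormal marginals with per-compartment scales.
Strict monotonicity preserves Spearman correlation, so planted pairs are
recoverable in rank-correlation networks. The default interaction plan
picks node-disjoint pairs (producer–producer positive, grazer–producer
negative), making the planted matrix block-diagonal and positive definite
by construction; arbitrary plans are repaired by eigenvalue clipping with
a warning. The default catalogue has 110 taxa (1 virus, 2 bacteria, 46
phytoplankton, 4 heterotrophic flagellates, 28 naked ciliates, 29
tintinnids) with uniform ESDs in fixed per-compartment ranges.

Fluorescence bloom windows are log-linear ramps (strictly positive daily
log growth during the window, strictly negative during a 7-day decay), so
a noise-free series is exactly recoverable by the bloom rules.

## Determinism

Every stochastic routine takes a seed or Generator; the pipeline derives
stage seeds from the single configured seed. Floats are written with the
`%.10g` format and JSON keys are sorted, so a rerun with the same seed
produces byte-identical output directories (asserted in the acceptance
suite) and `scripts/acceptance.py` output is byte-stable per seed.

## Limitations

- The run-based bloom rules assume smooth fluorescence. Unsmoothed iid
  daily noise creates spurious 2-day positive runs and suppresses 5-day
  negative runs, inflating detected blooms; `scripts/acceptance.py`
  reports the recovery Jaccard both noise-free (1.0 by construction) and
  under daily lognormal noise to quantify this. Smooth or pre-filtered
  input is expected in practice.
- Raw p < 0.05 edge filtering performs no multiple-testing correction;
  with thousands of pairs the networks contain false edges at roughly the
  nominal rate (the permutation type-I error is verified to sit at the
  nominal level).
- The ER null ignores the degree sequence; verdicts confound group-level
  enrichment with hub placement.
- Weekly samples are treated as exchangeable by the permutation test;
  autocorrelation is only diagnosed, not corrected.
- Spherical biovolume underestimates elongated taxa (e.g. tintinnid
  loricae); shape-specific formulas are out of scope.
- PELT class counts on uniform (clusterless) ESDs depend on the penalty
  and scale defaults; they are data descriptions, not ecological claims.
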