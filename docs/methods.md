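# Methods

This note documents the models and procedures implemented in `anchorscope`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make outputs
reproducible.

## Study design the package implements

The workflow is anchor-centric: one gene's expression defines every
analysis. Two cohorts are preprocessed and analyzed strictly separately and
meet only at two cross-cohort steps — the mean-correlation ranking and the
mean intermediary-ratio ranking. This mirrors the replication logic of
two-cohort microarray studies: intersecting independent analyses trades
some sensitivity for a lower false-positive rate.

## Preprocessing

Raw intensities are non-negative. Each cohort is filtered by per-gene
median intensity, with two dialects because published cohorts differ:

* `strictly_greater` — keep genes with median **>** threshold (e.g. "median
  expression greater than zero");
* `at_least` — keep genes with median **≥** threshold (e.g. "a median
  threshold of 1, reached by" a stated number of probes).

The median over an even number of samples is the mean of the two central
order statistics. After filtering, values map as v → log₂(v + offset). The
offset is not standardized across studies; the default of 1 maps zero
intensity to zero on the log scale, the most common microarray convention.
Both offset and log base are configurable. Probe-to-gene collapsing is not
modeled: one row is one gene symbol, and duplicated symbols are rejected at
parse time with a line number.

## Anchor correlation

For each non-anchor gene, Pearson r against the anchor on the log scale;
the two-sided p-value uses the exact transform t = r·√((n−2)/(1−r²)) with
n−2 degrees of freedom. |r| within one part in 10¹² of 1 is treated as
exactly ±1 with p = 0, so a duplicated anchor row does not produce a
spuriously finite p from float rounding. FDR adjustment is
Benjamini–Hochberg — the default meaning of "FDR" in transcriptomics —
applied to the family of all non-anchor genes *within one cohort*, matching
per-cohort adjusted-p reporting. The cross-cohort table inner-joins the two
cohorts' gene sets and ranks by the arithmetic mean of the two r values.

## Random-forest feature selection

The anchor is regressed on all other genes with extremely randomized trees
(random split thresholds, no bootstrap resampling of rows), the
`extratrees` split rule of the ranger/caret ecosystem, here provided by
scikit-learn's `ExtraTreesRegressor`. ranger's `min.node.size` gates
whether a node may still be split, so it maps to `min_samples_split`.
Defaults follow the published design this reproduces: mtry ∈ {5,…,50 step
5}, minimum node size ∈ {2, 3}, 101 trees, five repeats of 10-fold CV.
RMSE is the tuning metric (the conventional default of that ecosystem);
R² and mean absolute error are reported alongside. Grid ties go to the
earlier cell (lowest mtry, then node size). The final model is refit on all
samples — the resampling procedure only selects hyperparameters — and
impurity (variance-reduction) importances from that refit are scaled so the
maximum is exactly 100, the convention that makes importance tables
comparable across cohorts. Cross-cohort intersection keeps genes strictly
above a threshold (40 or 70 by convention) in *both* tables.

## DRAIMI

A transcript ratio for genes (a, b) is, on the log scale, the per-sample
difference d_s = x_a,s − x_b,s. The two groups compared are the upper and
bottom deciles of anchor expression: group size ⌊f·n⌋ (minimum 1) with
f = 0.10 by default; samples are placed on one total order by (anchor
value, sample id), the bottom k forming the lower group and the top k the
upper group, which makes boundary ties deterministic and the groups
disjoint by construction.

Each pair's differential statistic is the absolute Welch two-sample t on
d between the groups (robust to unequal group variances; the statistic is
pluggable). Consistency comes from a within-group bootstrap: group sizes
are preserved, samples are resampled with replacement inside each group,
and a pair's consistency is the fraction of replicates (default 100) in
which its |t| ranks inside the top `per_bootstrap_k` pairs (default equal
to `top_k`, default 1000). Final ranking: consistency desc, observed |t|
desc, pair-lexicographic. Degenerate groups of size one contribute zero
variance; a zero pooled standard error yields |t| = 0 when the group means
agree and +∞ when they differ, so constant-difference pairs sort sensibly.

Pivot scoring: for every network gene g with degree ≥ 1, hits = the number
of top-K ratios (a, b) with g distinct from both members and edges {g,a}
and {g,b} both present; the intermediary ratio is hits / degree(g), with
the degree taken in the full loaded graph. Pairs containing g itself are
excluded — an intermediary stands between two *other* proteins. Zero-hit
nodes are kept with score 0; zero-degree nodes are excluded with a counted
warning. Note that hits is bounded by K, not by degree: in a dense graph a
node's neighborhood can contain more top ratios than the node has edges,
in which case the score exceeds 1 (`C(d,2) > d` for degree ≥ 4). In the
method's operating regime — sparse, confidence-thresholded interaction
networks and K small relative to the pair universe — the score behaves as
a [0, 1] fraction, and the test suite covers both regimes explicitly.

The anchor is excluded from the ratio gene set by default (its deciles
define the groups; including it would rank anchor-containing ratios by
construction), with a flag to include it. The cross-cohort table
inner-joins per-cohort pivot scores and ranks by their mean.

## Synthetic-data generator

The generator emulates a two-cohort microarray study with known ground
truth. Per gene, a latent standard-normal signal per sample is mapped to
log2 scale as μ_g + σ_g·latent with per-gene location and scale drawn once
from uniform ranges (defaults μ ∈ [4, 10], σ ∈ [0.3, 1.0], typical of
log2 microarray intensities). Planted structure:

* a correlate with target r uses latent r·z + √(1−r²)·ε, z being the
  anchor's latent signal, so the target correlation holds exactly on the
  log scale in expectation (and exactly for |r| = 1);
* a ratio pair (a, b, s) moves a's log values up by s/2 and b's down by s/2
  for top-anchor-decile samples, so d = x_a − x_b shifts by exactly s
  between deciles while pairs sharing only one member shift by s/2 and stay
  dominated;
* each pivot is wired to both members of its assigned ratio pairs;
  background edges are independent Bernoulli draws.

Log values become intensities via 2^v − offset, clipped at 0 — the exact
inverse of the preprocessing transform, so planted structure is recovered
on the analysis scale (clipping perturbs only values ≈4σ below a gene's
mean, negligible at the default ranges). One global seed expands into
independent substreams for cohort 0, cohort 1, and the graph, so adding a
planted entity in one stream does not perturb the others, and identical
spec + seed reproduces outputs bit-for-bit.

What the generator does **not** emulate: probe-level bead noise, control
probes, batch effects, covariates (age, sex, smoking), heavy-tailed or
correlated background structure, and probe-to-gene multiplicity. Passing
tests therefore demonstrate algorithmic correctness and recovery under an
idealized Gaussian co-expression model, not robustness to real microarray
artifacts.

## Problem sizes and defaults used in the checks

Recovery checks run on two cohorts of 400 and 300 samples × 200 genes with
planted r ∈ {0.75, 0.5, −0.55}, one ratio pair (shift 2.5 log2 units), one
pivot, and no background edges; the DRAIMI gene set is the pair members
plus ten background genes with top-K = 5, and the forest is tuned over a
reduced grid (mtry {5, 15, 30} × node size {2, 3}, one 5-fold CV repeat)
— sizes chosen so a full run finishes in minutes on a laptop while leaving
the planted effects comfortably above sampling noise. The full default
grid is exercised separately at a small matrix size. The null calibration
uses a 500-sample, 200-gene cohort with nothing planted.

## Report-file conventions

Correlation coefficients, importances, and intermediary ratios are written
to two decimals with ties rounded half away from zero (0.125 → 0.13,
−0.125 → −0.13); adjusted p-values use three significant digits. Rounding
applies only at the file boundary — all chained computation is full
precision. Ranking ties anywhere break by gene-symbol lexicographic order.
The pipeline manifest records input SHA-256 hashes, the defaults-filled
config echo, per-stage survivor counts, and the seed; re-running from the
same config and inputs reproduces every report file byte-for-byte.

## Known limitations

* The bootstrap consistency statistic and its replicate count are design
  choices (the ratio statistic is pluggable); other operationalizations of
  "most consistently differing" would reorder near-tied pairs.
* The intermediary ratio is not normalized across degrees: a degree-1 node
  adjacent to one top ratio scores 1.0, outranking hubs with many hits.
  Interpreting the ranking requires the hits and degree columns that the
  report table includes.
* `mtry` grids assume at least as many predictors as the smallest grid
  value; larger values are dropped with the grid, never silently clamped.
* Correlation p-values assume bivariate normality on the log scale; with
  heavy-tailed real intensities the FDR calibration is approximate.
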