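# Methods

## Setting

A panel of ion-channel baits is immunoprecipitated in quadruplicate from the
same membrane-enriched tissue lysate and measured by label-free MS, together
with IgG control pulldowns and deep proteome measurements of the input
lysate. Because many baits are processed in parallel, the panel itself
provides each bait's specificity control: a protein that appears at similar
intensity in most pulldowns is a background binder, while a true interactor
is enriched only in its bait's replicates. The package implements that
comparison and everything downstream of it.

## Normalization

Raw intensities are strictly positive; upstream zeros are non-detections and
become missing at ingestion. Pulldowns (including IgG columns) and proteomes
are quantile-normalized separately, then log2-transformed. The normalization
maps every column onto the common reference distribution given by the
row-means of the column-sorted matrix; with missing values, the reference is
interpolated onto each column's observed quantiles, so missing entries stay
missing and within-column rank order is preserved. Ties receive the mean of
the reference values their positions span. On complete data the transform is
idempotent, and it agrees with Bioconductor limma's `normalizeQuantiles`
(checked in the test suite via `Rscript`).

## Control cascade

Eligibility for complementary-median controls uses the strict more-than-half
rule over all bait pulldown replicates (IgG columns excluded): with 16
pulldowns × 4 replicates, a protein must appear in more than 32 of the 64
samples. Controls are then assembled per protein and per replicate slot:

1. **Complementary medians.** The test needs a control vector with the same
   replicate count as the bait side, while a complementary median is a
   single number. We therefore take, for replicate slot r, the median over
   the out-of-family baits' r-th replicate values. This keeps the control
   side's values centred on the complementary median while giving them
   realistic replicate-to-replicate spread; four identical copies of one
   grand median would make the control variance exactly zero and distort
   both the pooled standard error and the permutation distribution. The
   scalar `complementary_median` (median over *all* out-of-family replicate
   values) is also exposed for reporting. Family exclusion is total: all
   baits sharing the target's family label are removed before the median.
2. **IgG.** Slots still missing (or proteins failing eligibility) take the
   observed IgG values slot-wise (slot r ← IgG replicate r, cycling if
   fewer IgG replicates exist).
3. **Scaled proteome.** Remaining slots take the protein's median value in
   the deep proteome after an affine map on log2 scale fitted on the shared
   proteins so that scaled median and IQR equal those of the pulldown
   matrix. The exact scaling procedure of the original approach is not
   fully specified; median/IQR matching is the simplest robust affine
   anchor and is flagged here deliberately. A zero-IQR proteome either
   errors or applies a median-only shift, per config.
4. **Left-shifted random imputation.** Anything left is drawn from
   N(μ − 1.8σ, (0.3σ)²), with μ, σ the mean and SD of all observed
   normalized log2 pulldown values. Width 0.3σ and downshift 1.8σ are the
   conventional defaults for left-censored label-free MS imputation; both
   are configurable.

Provenance (complementary_median / igg / proteome_scaled / random_imputed)
is recorded per control value and reported per protein. Missing bait-side
values (at most 1 of 4 after the replicate filter) are imputed per column
from the same left-shifted model.

## Test statistic and FDR

For bait values x and control values y,

    d = (mean(x) − mean(y)) / (se_pooled + s0),

with the pooled (Student) two-sample standard error; s0 (default 2) makes
the significance boundary depend on the fold change as well as the
p-value — as s0 grows, d approaches Δmean/s0. The reported p-value is the
classical two-sided pooled t-test p; s0 enters only the cutoff geometry.
At s0 = 0, d is exactly the classical t statistic.

Proteins observed in fewer than `min_valid_replicates` (default 3) of the
bait's replicates are excluded before testing. The FDR at a candidate
threshold c on |d| is the mean permuted count of |d| ≥ c divided by the
observed count, capped at 1, where permutations relabel bait vs control
columns jointly for all proteins (preserving protein-wise correlation).
The significant set is |d| ≥ c* for the smallest candidate with FDR ≤ q
(default 0.05). With ≤ 8 total columns — the standard 4 vs 4 case has
C(8,4) = 70 assignments — enumeration is exact; otherwise 250 random
relabelings are drawn (configurable). Per-bait (q, s0) overrides allow
relaxing low-abundance baits or tightening promiscuous ones; no tweaked
values are hard-coded. An unreachable target yields an empty significant
set, not an error.

## Synthetic data

The AP-MS generator draws per-protein base abundances N(25, 2²) on log2
scale with N(0, 1²) replicate noise, spikes each bait's true interactors
(including the bait protein itself) by +4 log2 units in that bait's
replicates only, and draws IgG columns from background. Missingness is
logistic left-censoring in log2 intensity: P(missing | x) = 1/(1 + exp(s·(x
− x0))), with the midpoint x0 calibrated by bisection so the realized
overall missing fraction matches the requested 25 % (±2 %); the deep
proteome uses the same model at 5 %. Defaults (6 baits × 4 replicates,
2,000 proteins, 20 true interactors per bait) are the conditions used by
the calibration tests; abundance means and spreads are free parameters, not
claims about any real dataset. The generator does *not* emulate
peptide-level effects, match-between-runs, correlated background binders,
batch structure, or intensity-dependent variance — so passing calibration
here shows the statistics are internally consistent, not that real screens
will achieve the same operating point.

The expression generator builds cardiomyocyte subpopulation columns from a
shared latent factor with loading √r so their pairwise Pearson correlation
equals the target r, sets a planted fraction of genes to zero in all CM
columns, and keeps values non-negative. The ECG-GWAS generator gives null
genes Uniform(0,1) variant × timepoint tables and plants, for signal genes,
exactly one entry at the requested minimum (all other entries rescaled
strictly above it). The cluster-image generator places discs of radius 2–5
px; "proximal" A-clusters share at least one pixel with a B-cluster
(edge-to-edge distance 0 < 1 px), distal ones keep a continuous gap ≥ 3 px,
and B-clusters are mutually far apart so each proximal A touches exactly
its partner. Truth and measurement share one definition of adjacency, so
recovery is exact by construction.

## Cluster proximity

Channels are smoothed (Gaussian, σ configurable), binarized (Otsu or fixed
threshold), and labeled with 8-connected components (4-connectivity
available); components below a minimum pixel area are discarded. The
per-cluster distance is the minimum edge-to-edge Euclidean pixel distance
to any pixel of the other channel, computed with an exact Euclidean
distance transform; overlap gives 0. Two clusters are separate when the
gap is at least 20 nm (one pixel at the default 20 nm/px), proximal when
strictly below. The summary is directional — the fraction of channel-A
clusters proximal to channel B. Smoothing σ, threshold and minimum area
are exposed and logged, as no canonical values exist for them.

## ECG annotation

Each gene's signal is the global minimum p over its LD-block variant ×
timepoint table (ties: first variant, then first timepoint). LD blocks are
input data, not computed. The cutoff is α / n_indep / N with α = 0.05,
n_indep = 80 effectively independent tests for the 500-point ECG cycle
(an external estimate, configurable), and N the number of genes actually
tested; significance is strict (min_p < cutoff). Genes without tables are
reported untested and excluded from the summary denominator.

## Numerical and design notes

- The significance direction is FDR ≤ q with s0 fixed at its configured
  value; the moderated |d| is non-increasing in s0.
- Degenerate tests (both sides constant) give d = 0, p = 1 when means
  agree, p → 0 otherwise; p-values are clipped away from 0 before logs.
- Permutation seeds derive from the pipeline seed plus the bait index, so
  per-bait results are independent of bait order and bit-reproducible.
- Ranking for follow-up is a total order: lexicographic descending on
  (replicates identified, sequence coverage, peptide specificity) with an
  ascending protein-id tie-break. Peptide specificity is the bait-IP count
  minus the *maximum* count in any other IP.
- Whether baits count in the human-presence and expression denominators is
  a flag (off by default).
- Known-interactor evidence comes from user-supplied score tables filtered
  at ≥ 0.4; no live database queries.

## Problem sizes

The calibration tests and the acceptance script use 10 simulated screens of
2,000 proteins × 6 baits (plus matched null screens), 1,000-gene expression
matrices, 1,000 genes × 10 variants × 500 timepoints of GWAS tables and
256×256 px cluster images with 20 clusters per channel; the whole suite
runs in well under a minute on one CPU.

## Limitations

Protein inference, match-between-runs and peptide-level modelling are out
of scope; the pipeline starts from a protein-group intensity table. The
scaled-proteome step assumes the deep proteome and pulldown intensity
distributions differ by an affine log2 map. The permutation FDR with four
replicates has a resolution floor of 1/70 per enumeration; calibration
below that is meaningless. Cross-referencing between protein, gene and
transcript identifier namespaces is left to the caller — the pipeline
treats identifiers as opaque strings until ortholog mapping.
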