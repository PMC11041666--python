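# ionnet

Interactor calling for panels of parallel immunoprecipitation–mass
spectrometry (AP-MS) experiments, aimed at cardiac ion-channel interactomes:
many baits are pulled down in replicate from the same tissue lysate, and the
panel itself provides the specificity control for each bait. The package
covers the full downstream path: enrichment statistics, interaction-network
assembly, human-relevance annotation (heart proteome presence, cardiomyocyte
expression, ECG-GWAS significance) and super-resolution cluster proximity —
plus a synthetic-data generator so every stage is testable without access to
a deposited raw dataset.

## The statistical model

For each bait, a protein's four replicate pulldown intensities are compared
against a control distribution assembled in a cascade:

1. **Complementary medians** — for proteins observed in more than half of
   all bait pulldown replicates (e.g. >32 of 16×4 = 64), the control is the
   median of the protein's normalized intensities across the *other*
   pulldowns, excluding the target bait's whole family (so closely related
   channels such as the Kcnj2/Kcnj3/Kcnj5 inward rectifiers cannot mask each
   other's shared partners);
2. otherwise observed **IgG control** pulldown values;
3. otherwise the protein's value in a **deep proteome** of the same lysate,
   affine-scaled (median/IQR matched) onto the pulldown intensity scale;
4. otherwise a draw from a **left-shifted normal** distribution
   N(μ − 1.8σ, (0.3σ)²) on log2 scale, the standard imputation model for
   left-censored (MNAR) missingness in label-free MS.

Intensities are quantile-normalized (pulldowns and proteomes separately) and
log2-transformed. Proteins observed in fewer than 3 of 4 bait replicates are
excluded. Enrichment is tested with an s0-moderated two-sample statistic

    d = (mean_bait − mean_control) / (se_pooled + s0)

where s0 (default 2) weighs the fold change against the p-value, and
significance is called at a permutation-estimated false discovery rate
(default q = 0.05): bait/control column labels are permuted jointly across
proteins, exactly enumerated when at most 8 columns are involved (a 4-vs-4
comparison has 70 distinct assignments).

Called interactors feed a combined bait–interactor network (with
channel–channel edges when one bait precipitates another), shared-interactor
intersections, lexicographic prioritization (replicate count, sequence
coverage, peptide specificity), ortholog mapping with an uppercase fallback,
expression funnels, and per-gene ECG-GWAS annotation: the minimum
association p across a gene's LD-block variants and 500 ECG timepoints,
against a Bonferroni cutoff α / 80 / N (80 effectively independent ECG
tests, N proteins tested; 0.05/80/10 = 6.25×10⁻⁵).

## Worked example

```bash
ionnet demo --seed 1 --out demo/
```

runs the full chain on one synthetic dataset (2,000 proteins, 6 baits × 4
replicates, 20 true interactors per bait spiked at 4 log2 units, 25 %
MNAR missingness) and prints:

```json
{
  "recall": 0.9210526315789473,
  "realized_fdr": 0.03669724770642202,
  "n_interactors": 107,
  "percent_detected_human_heart": 91.58878504672897,
  "percent_cm_expressed": 99.06542056074767,
  "percent_ecg_significant": 50.467289719626166,
  "storm_truth_fraction": 0.3,
  "storm_measured_fraction": 0.3
}
```

Reading: 92 % of the spiked ground-truth interactors were recalled at an
observed false-discovery proportion of 3.7 %; of the 107 network
interactors, 91.6 % were present in the (synthetic) human heart proteome
list and 99.1 % expressed in a cardiomyocyte subpopulation; half the genes
carried planted ECG signals and exactly those were flagged; and the
constructed 30 % two-channel cluster proximity was measured back exactly.
Per-bait volcano tables, the GraphML network, the ECG table and a manifest
with the config and seed land in `demo/`.

Individual stages are available as `ionnet simulate|call|network|omics|ecg|storm`;
the same functionality is importable from the `ionnet` package.

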