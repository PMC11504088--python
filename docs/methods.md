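# Methods

`regulomics` integrates transcription-factor ChIP-seq peak sets with
knockdown RNA-seq to identify direct regulatory targets, distil them into
compact metagene signatures, and evaluate those signatures on tumor/normal
cohorts.  The motivating use case is a pair of lineage-survival transcription
factors (GATA4 and GATA6 in gastric cancer): both bind chromatin genome-wide,
both were depleted by inducible shRNA, and the question is which coding and
non-coding genes they directly regulate and whether those targets carry
diagnostic or prognostic information.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic study
conditions do and do not establish.

## Peak-to-gene annotation

Coordinates are 0-based half-open throughout; GTF input (1-based inclusive)
is converted on read, and multi-transcript genes collapse to a single
canonical TSS (the most upstream transcript start).  Each peak is assigned to
the gene with minimal |summit − TSS|, with ties broken by lexicographic
gene id for determinism.  Distance is measured summit-to-TSS because the
summit is the best point estimate of the binding site, and it is
strand-oriented (upstream negative).  Distance categories are bins on
|distance| — [0,1), [1,3), [3,5), [5,10), [10,100), [100,∞) kb by default —
and are configurable because promoter sub-binning conventions differ between
analyses.  Binding both upstream and downstream of the TSS counts toward the
same bin, since TF presence is frequently intragenic.

Enrichment over background divides each category's peak density
(peaks per bp of category territory) by the genome-wide density.  Territory
is computed exactly: between consecutive TSSs the nearest-TSS distance is a
pair of linear ramps, so the bp whose distance falls in each bin follows from
interval arithmetic.  A ratio of 1 means a category holds exactly the share
of peaks its size predicts; distal categories are large, which is why raw
peak percentages overstate distal binding.

Co-occurrence of two peak sets uses the relative-distance statistic: for each
query midpoint lying between two consecutive reference midpoints at distances
d_left and d_right, the statistic is min(d_left, d_right)/(d_left + d_right)
∈ [0, 0.5].  Under spatial independence it is uniform; an excess near 0
indicates co-localization.  Query midpoints outside the reference span are
skipped, as are chromosomes with fewer than two reference midpoints.

## Regulatory score

The per-gene score follows the target-identification-from-profiles idea: a
genome-wide average binding profile around the TSS is learned first, then
each gene is scored by the profile-weighted sum of its own signal.
Concretely, signal(d) for a gene is the summed signalValue of peaks covering
the genomic point at strand-oriented offset d from the TSS (peak signal is
painted uniformly across the peak interval, because only peak-level data are
in scope).  The profile is the per-bin mean over genes, smoothed with a
5-bin moving average (nearest-edge padding, so a flat profile stays exactly
flat) and normalized to sum 1.  Defaults: window ±100 kb, 100 bp bins —
regulatory binding is observed out to 100 kb while the learned weights
concentrate near the TSS on promoter-driven data.  The raw score is
Σ_d w(d)·signal(d): nonnegative, zero iff no in-window signal, and monotone
in added signal.

Scores are z-normalized (sample sd over all genes) and calibrated so the
median of strictly positive raw scores maps to 10; zeros are excluded from
the median so sparse inputs cannot collapse the scale.  This makes the
selection threshold "score ≥ 10" mean "at or above the positive-score
median", and the calibration is a positive multiple of raw, so rankings are
unchanged.  Two TFs' scaled scores combine elementwise (mean by default; min
and max available — the min-mode threshold set is contained in the mean-mode
set, which is contained in the max-mode set).

## Knockdown differential expression and integration

Counts are normalized to log2 CPM (log2(1e6·c/libsize + 1)).  The default
test is a per-gene Welch two-sample t on log-CPM with Benjamini–Hochberg
correction; externally produced DE tables with columns
(log2fc, p, p_adj, mean_expr, biotype) can be substituted, so the
integration is not tied to this test.  Genes constant in both groups with
equal means get p = 1; degenerate infinite t statistics are floored at
p = 1e-300 to keep p ∈ (0, 1].  DEG classes use an inclusive fold-change
gate interpreted on the linear scale (|log2fc| ≥ log2 1.25 by default, with
a flag for the literal log reading) and p_adj ≤ α.

The deregulogram records each gene's fold-change pair across the two
knockdowns, its significance class, and concordance (same fold-change sign);
the summary reports Pearson r and percent concordant over genes significant
in both contrasts.  The score-vs-deregulation trend sorts genes by ascending
combined score and takes a centered 200-gene rolling mean of fold change
(window shrunk at the edges; ties in score broken by gene id).  The window
size is a smoothing choice, not an inference parameter.

## Signature selection

A gene enters the panel iff (i) combined scaled score ≥ 10, (ii) it is
significantly deregulated in the same direction in both knockdowns, and
(iii) its fold change passes the ±1.25 linear gate in both.  "Equally and
unidirectionally affected" is operationalized as same-direction
significance; an optional stricter mode additionally requires
|fc₁ − fc₂| ≤ 0.5 log2 units.  Admitted genes split into four disjoint
signatures: coding/non-coding × up/down, with "coding" = protein_coding and
"non-coding" = everything else (lincRNA, pseudogene, other).  Selection is
an intersection of criteria, so relaxing any one criterion can only grow the
panel, and the output is deterministic and order-invariant.

## Cohort evaluation

Tumor and normal expression matrices are merged on their shared gene
universe, each sample is upper-quartile-scaled to a fixed target (1000; the
upper quartile is taken over positive values, and a fixed target makes
rescaling any single sample exactly invisible downstream), values are
log2(x+1)-transformed, and each gene is z-scored over the pooled cohort
(population sd; zero-variance genes dropped).  Quantile normalization is
available as an alternative.  A signature's per-sample metagene score is the
mean z over its genes.

ROC analysis uses Mann–Whitney pair counting with ties counted 1/2
(identical to the trapezoidal area under the empirical ROC curve), a
Hanley–McNeil normal-approximation 95% CI, and the Youden-optimal operating
point.  Down-signatures legitimately score AUC < 0.5; tables report both auc
and 1 − auc.  Per-stage ROC compares each stage's tumors against all
normals; stages with fewer than 3 tumors are skipped.

Survival stratification dichotomizes tumors at the median metagene score
(ties to the low group, the common convention and deterministic), compares
groups with the standard log-rank test (lifelines), and emits Kaplan–Meier
step tables.  The worse-survival direction comes from the observed-vs-
expected event tally of the high group.  The median split makes the test
invariant under any strictly monotone transform of scores.  Strata
comparisons use Kruskal–Wallis plus BH-adjusted pairwise rank-sum tests;
the multi-cohort panel applies the tumor-vs-normal rank-sum test per cohort
with BH across cohorts and takes direction from the median difference.

## Synthetic study conditions

The generator produces one 50 Mb chromosome with 2000 genes (70% coding;
non-coding split lincRNA/pseudogene/other ≈ 5:3:2), gene lengths lognormal
around 10 kb.  200 planted direct targets receive a promoter peak within
±1 kb of the TSS for both TFs with LogNormal(μ=2, σ=0.5) signal (plus an
optional distal peak with probability 0.3); all genes sit over a uniform
background of 5 peaks/Mb with LogNormal(1, 0.5) signal.  Counts are negative
binomial (var = μ + 0.1·μ², a typical bulk RNA-seq dispersion scale) with
lognormal baseline means (median ≈ 55 counts), 4 control vs 4 knockdown
samples per TF, and planted log2 fold changes ±Uniform(0.5, 1.5) with the
sign shared across the two TFs (75% up).  The cohort has 100 tumors and 50
normals; planted signature genes shift by 1.5 per-gene z-units in tumors,
and tumor survival is exponential with log-hazard 0.8 × the up-signature
metagene z and uniform censoring on (0, 40).  Every output is a
deterministic function of the seed (independent sub-streams per stage), and
a truth ledger records all planted effects.

What the fixtures do not emulate: library-specific GC or length bias,
correlated gene modules, batch effects, tumor purity, multi-chromosome
genomes (optional), or read-level data.  Passing recovery tests therefore
demonstrates internal consistency of the pipeline under its own assumptions,
not performance on real cohorts.

A deliberate property of these conditions is that 4-vs-4 replication at
dispersion 0.1 gives limited per-gene power: an oracle z-test with known
variance detects a 0.5–1.5 log2 shift after BH correction over 2000 genes
less than half the time per contrast, and the joint two-contrast requirement
roughly squares that.  The default fixture consequently yields high raw-p
detection (~50–60% of planted genes per contrast at p ≤ 0.05) but a small or
empty BH-gated panel — an honest reflection of minimal-replication designs
rather than a pipeline defect.  The test suite demonstrates near-complete
BH-gated recovery at 16-vs-16 replication.

## Numerical choices and edge cases

- BH-adjusted p is floored at its raw p and clipped to (0, 1].
- The profile smoother clips sub-epsilon negatives introduced by the
  uniform filter; binned signal from the cumulative-sum coverage is clipped
  at 0 against float cancellation.
- Peaks on chromosomes without genes annotate to no gene in the most distal
  category with a warning; genes missing from one TF's score table combine
  as score 0 with a warning; panel genes absent from a cohort matrix are
  logged and skipped (error only if none remain).
- All tie-breaks (nearest-TSS gene, trend sort, median split) are
  deterministic and documented at the definition site.

## Reported problem sizes

The acceptance script and test suite run the full pipeline at the default
conditions above (2000 genes, ~500 peaks per TF, 8 samples per contrast,
150-sample cohort), 2000-replicate permutation nulls for type-I checks, and
100-replicate survival recovery — sizes chosen so that every stochastic
check is stable across seeds while the whole suite completes in about a
minute on one core.
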