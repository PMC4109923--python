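# Methods

## Problem setting

Short-term (hours to weeks) rat exposure experiments produce log2-scale
expression matrices with a characteristic design: each chemical is
administered at several dose levels and exposure times, in triplicate,
alongside vehicle-control animals kept in matched conditions. The
long-term phenotype — carcinogenicity in the 2-year rodent bioassay —
is known per compound (sometimes per compound-dose). The package models
the full analysis chain from such matrices to a carcinogenicity
classifier and its biological characterization.

## Data model

`ExpressionDataset` binds a genes × samples matrix (assumed log2 scale;
fold changes are `2^(mean difference)`) to per-sample metadata
(compound, dose level, time, replicate, tissue, batch, control flag).
Controls carry the literal compound string `CONTROL`. Matched controls
are resolved through a `control_group_id`, derived as the
(tissue, time, batch) triple unless the metadata supplies an explicit
column; the dataset validates on construction that every treated sample
resolves at least one control in its own tissue and batch. All tabular
I/O is UTF-8, tab-delimited, `.`-decimal; identifiers are opaque
strings (no probe/symbol mapping is attempted, and values are written
with Python's shortest round-trip float representation so read∘write is
exact).

## Perturbational transcriptome

Per compound instance (one column per compound, or per compound@dose
when a compound was profiled at several dose levels), treated samples
are pooled across exposure times against the union of their matched
controls, and each gene receives the Wald *t* of the treatment
indicator in the OLS fit `expression ~ treatment + C(time)`. Time
enters as a categorical covariate because the response ramps with
exposure duration and treated/control samples may be distributed
unevenly across times; with a single time level the statistic reduces
exactly to the pooled two-sample *t* (verified against scipy). A design
in which time is collinear with treatment is flagged and its column set
to NaN rather than fitted. q-values are Benjamini–Hochberg within each
instance across genes; BH is used for every FDR correction in the
package (the in-package step-up implementation is cross-checked against
statsmodels in the tests).

A gene is *responsive* if q ≤ 0.01 and fold change ≥ 1.5 (two-sided:
fc ≥ 1.5 or ≤ 1/1.5) in at least five instances; instance counting is
the default, with an option to count distinct compounds once. Gene-wise
association with carcinogenicity is a two-sided Fisher exact test on
the 2×2 table (differentially expressed × phenotype positive) over
compounds with known labels, BH-corrected, with the direction taken
from the Haldane-smoothed odds ratio.

Compound clustering is agglomerative with average linkage on
1 − Pearson correlation between *t*-score columns, cut at k = 2 —
correlation distance being the field's default for expression
signatures. Cluster-phenotype association is again Fisher; the
difference in per-compound counts of regulated genes between clusters
is a two-sample Kolmogorov–Smirnov test.

## Moderated t signatures

The phenotype contrasts (carcinogenic vs not; genotoxic vs not;
genotoxic vs non-genotoxic within carcinogens; non-genotoxic
carcinogens vs double negatives) are tested with a self-contained
empirical-Bayes moderated *t*. With per-gene pooled variances s²_g on
d residual df, the prior (d₀, s₀²) is estimated by method-of-moments on
z = log s²_g, using E[z] = log σ² + ψ(d/2) − log(d/2) and
Var[z] = ψ′(d/2): the excess of the observed variance of z over
ψ′(d/2) is inverted through the trigamma function to give d₀ (with
d₀ = ∞, i.e. complete shrinkage, when there is no excess). The
statistic is t̃ = Δmean / √(s̃²(1/n_A + 1/n_B)) with
s̃² = (d₀s₀² + d·s²_g)/(d₀ + d) on d₀ + d df. Exact numerical parity
with any external fitting package is a non-goal; the limiting behaviors
(d₀ → 0 recovers the ordinary pooled t, d₀ → ∞ shares one variance) and
the shrinkage MSE gain at n = 3 are tested instead. Replicates of the
same condition are averaged before testing so repeated profiles do not
inflate significance.

Pre-ranked enrichment uses the weighted-KS enrichment score (below)
with a gene-permutation null at fixed set size,
p = (1 + #{|ES_perm| ≥ |ES|})/(1 + n_perm), BH across sets. A
gene-permutation null was chosen over phenotype permutation for
determinism at small sample counts; it conditions on the observed
ranking and is therefore insensitive to inter-gene correlation, which
is acceptable at desk scale and is flagged here as the main caveat.
Hyper-enrichment of a top-gene list is the one-sided hypergeometric
tail. PCA is a centered SVD over samples with each component's sign
fixed by its largest-magnitude loading.

## Gene-set projection

Each treated sample is compared with its matched controls:
z_g = (x_g − mean(ctrl_g)) / (sd(ctrl_g) + ε), ε = 10⁻⁶. Genes are
ranked by descending z (ties broken by gene id), weights are |z|
(weight exponent 1, the standard weighted statistic). Walking the
ranking, the hit curve climbs by w_g/Σ_set w at member genes and the
miss curve by 1/(N − |set|) elsewhere; the enrichment score is the
running difference of maximal absolute value, signed. All-zero weights
give ES = 0 by convention; a set covering the whole universe is
rejected. With a single control the per-gene spread is undefined and a
scalar fallback — the standard deviation across genes of the
treated-minus-control differences — replaces it. Controls are pooled
across replicates rather than averaged first.

This is deliberately *not* the rank-weighted single-sample GSEA
variant: the ranking statistic is true treatment-vs-control
differential expression, so every sample is normalized against controls
from its own batch, which is what makes the projected features robust
to additive dataset shifts. No normalized-ES variant is computed.

## Classification and evaluation

The default classifier is a 500-tree random forest whose score is the
probability of the compound being carcinogenic; linear-SVM and nearest
shrunken-centroid models plug in behind the same fit/score interface
for comparison. Feature selection — top-n by training variance, or by
|two-sample t| against the phenotype, including k-th-block selection —
runs strictly inside each training split.

Evaluation is a repeated 70/30 train/test split **at the compound
level**, stratified by label (per-class test quotas by largest-remainder
rounding, at least one test compound per class, remainder to train),
each iteration seeded deterministically from the master seed. Reported:
mean AUC (Mann–Whitney with half-credit ties) with the
normal-approximation 95% CI mean ± 1.96·SD/√n_iter, first/third-quartile
ROC bands on a common FPR grid, and a cost-thresholded metric suite.
The operating threshold minimizes fp_cost·FP + fn_cost·FN over the
*out-of-bag* training probabilities (ties resolve to the lowest
threshold): in-sample forest probabilities are nearly separable by
construction, which would make every cost ratio choose the same
degenerate threshold; OOB scores are still training-data-only, so no
test information is used. Per-compound aggregation (arithmetic mean of
replicate probabilities) is available behind a flag for both resampling
and external validation. Permutation variable importance is the
increase in training error when one feature's values are permuted,
averaged across iterations; importance-based feature rankings for the
feature-count sweep are computed within training splits by default.

Learning curves down-sample compounds (label-stratified) before the
70/30 resampling and fit an OLS line to the (size, mean AUC) pairs;
stratified grids run the evaluation per (time, dose) stratum, skipping
single-class strata with a flag. Confidence filtering keeps
probabilities > 0.66 (positive) or < 0.33 (negative) and drops the
middle band.

## Histopathology scoring

Pathology findings are ordinal covariates in {0..4} per sample
(nominally 133). The data-driven binary score is their logical OR —
positive iff any finding is non-zero — which is monotone by
construction. A manually curated score, when present in the table, is
consumed as given and never computed. Concordance of confident
classifier calls against either score reports accuracy, sensitivity,
specificity, PPV, NPV and FDR (= 1 − PPV), each with a Wilson 95%
interval over its own denominator.

## Synthetic cohort generator

The generator is the package's study-design stand-in, built for
parameter recovery rather than biological realism. Per gene a baseline
μ_g ~ N(8, 2) is drawn once; samples add N(0, noise_sd²) noise
(default 0.4, within the realistic range for normalized microarray
replicates and chosen so planted effects are recoverable at the
package's desk-scale cohort sizes), an additive gene-wise batch shift
N(0, batch_shift_sd²) drawn once per batch, and the planted effect.
Mechanism modules are disjoint gene blocks (default five modules of 50
genes in a 1000-gene universe), each unidirectional (up with
probability 0.7). Every carcinogen activates one mechanism module —
assigned round-robin over a shuffled carcinogen order so each mechanism
is represented and the assignment is independent of the (also
round-robin) batch assignment — and genotoxic carcinogens additionally
activate a designated damage-response module. The shift is
effect_size × dose multiplier × time ramp × direction, with dose
multipliers (0.3, 0.6, 1.0) for low/middle/high and a linear time ramp
from 0.5 at the shortest exposure to 1.0 at the longest, so classifier
accuracy rises with dose and time as it should. Controls are generated
per (tissue, time, batch) stratum (default 3); a single tissue is
generated by default. Defaults emulate a ~40-compound cohort with a
third carcinogenic, 40% of those genotoxic, three doses, four times
(4–29 days) and triplicates; the seed fully determines the output.

Companion generators emit: gene sets (exact module membership plus
random decoys, names flagging which is which), ordinal pathology
covariates calibrated so that P(any finding) equals a chosen
sensitivity for carcinogen-treated samples and P(all zero) a chosen
specificity elsewhere, and binary structural features correlated with
the label through flip noise.

What the generator does **not** emulate: probe-level artifacts,
correlated gene-gene noise within modules beyond the shared mean shift,
dose-dependent toxicity confounds, tissue mixtures, or realistic
effect-size distributions (no public estimate exists). Passing tests
therefore demonstrate that the pipeline recovers what it is designed to
recover under its stated assumptions — not that real cohorts carry
signal of this strength.

## Problem sizes and numerical choices

Validation experiments run at desk scale as the package's own choice of
study size: 500–1000 genes, 16–40 compounds, 3–20 resampling iterations
per configuration, and 10–20 generator seeds for seed-averaged
directional claims (dose/time gradient, learning-curve slopes,
cross-batch comparison). Null calibration of the resampling AUC spreads
its 50 iterations over five independent null cohorts because iterations
within one cohort resample the same compounds and are correlated, which
would understate the standard error of the mean. Degenerate inputs are
handled explicitly: all-constant genes give t = 0; singular designs
give NaN columns; empty responsive tables and single-class strata are
legal, flagged outputs. Fisher tests use the conditional two-sided
convention (sum of point probabilities ≤ the observed, with 10⁻⁷
relative tolerance in the enumeration oracle). Seeds derived from a
master seed use `numpy.random.SeedSequence` spawning and stay below
2³¹.

## Known limitations

- The gene-permutation enrichment null ignores inter-gene correlation;
  on strongly co-regulated modules its p-values are anti-conservative
  relative to a phenotype-permutation null.
- The moderated-t prior estimator assumes a common variance prior
  across the genome; a trended (intensity-dependent) prior is not
  implemented.
- Cross-batch robustness is demonstrated for additive gene-wise shifts
  only; multiplicative or nonlinear platform effects are out of scope.
- The compound clustering exposes only the k = 2 cut; the full
  dendrogram is not part of the public surface.
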