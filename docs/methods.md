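# Methods

`tbitriage` implements a staged triage of drug-repurposing candidates for
traumatic brain injury (TBI), from transcriptomic evidence through in
vitro biomarkers to a weighted go/no-go score, plus the machine-learning
evaluation of longitudinal in vivo biomarker panels. This note documents
the models, the defaults and why, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Transcriptomic signatures

A differential-expression table (gene, log2 fold change, BH-adjusted
FDR) is filtered into a directioned signature: a gene enters iff
|log2FC| > log2(1.5) **and** FDR < 0.05, both strict. Records whose FDR
is absent ("NA") are excluded — an undetected gene is missing evidence,
not evidence of change. Identifier translation (e.g. rat to human NCBI
IDs for connectivity-mapping queries) drops unmapped genes with a count,
expands one-to-many mappings to all targets, rejects collisions with
conflicting directions, and resolves same-direction collisions by the
smallest FDR (ties by lexicographic source ID — deterministic, and FDR
is the natural measure of evidence strength). Log2 effects convert to
percent of control as 2^log2FC x 100, rounded half-up when an integer is
requested.

## Concordance banding

Connectivity scores are ranked within the supplied candidate table by
**absolute** value (a strong negative concordance is still a strong
transcriptomic interaction). Percentile = rank/N with ties sharing the
*worst* percentile of the tied block, so ties never inflate a band.
Bands: top 10% → 5 points, then 4/3/2/1 per decile down to top 50%;
beyond that, 0. Two points of deliberate interpretation:

* The band ladder's 0-column is labelled from 60% in the source scheme
  but no 50–60% band exists; everything beyond the top 50% scores 0,
  following the stated "top 10%, 5 points; top 10–20%, 4 points, …"
  progression.
* Although ranking uses |concordance|, a compound whose signed score is
  negative earns 0 points by default (`negative_scores_eligible=False`):
  signature *reversal* is not rewarded unless the analyst opts in. This
  reproduces the published scorecards, where a negatively concordant
  compound scored 0.

## Co-culture assay analytics

Treated wells (pooled across replicate experiments, quadruplicates per
plate) are summarised as percent of the pooled untreated control and
tested with a two-sided Mann–Whitney U-test. The exact null distribution
is enumerated over all C(n, n_a) group assignments whenever
n_a + n_b ≤ 16, using midranks so ties are handled exactly; the
two-sided p is twice the smaller tail, capped at 1. Larger samples use
the tie-corrected normal approximation (scipy). Completely tied data
returns p = 1 (no separation is no evidence, not an error).

Banding: for the inhibition biomarkers (TNFα, nitrite) a significant
effect earns 5/4/3/2/1 points at ≤10/30/50/70/90% of control, 0 in
(90, 100], and −5 when a significant effect goes the wrong way
(> 100%). For viability the ladder mirrors upward: 1 point above 115%,
up to 5 above 300%, 0 in [100, 115], −5 for a significant decrease.
Edges are inclusive on the favourable side so an effect sitting exactly
on a band boundary earns the band. Non-significant effects always score
0. Per compound, the *strongest* significant concentration sets the
band (minimum percent for inhibition, maximum for viability), since the
scorecard assigns one value per compound across concentrations.
Dose-dependence compares two concentration groups by Mann–Whitney and
additionally requires the higher concentration's mean effect to be
directionally stronger.

The source scorecard contains one known irreconcilable cell: a compound
whose reported 12–26% TNFα reduction implies 1 point under any
consistent reading of the bands, yet is printed with 2 points. The
scoring engine reproduces the printed scorecards when fed the printed
points; the raw-percent route for that compound differs by one band.

## qPCR target engagement

Relative expression follows the ΔCt method, 2^−(Ct_gene − Ct_Gapdh).
Treatment effects are estimated on the −ΔCt scale — directly in log2
expression units — by OLS with a treatment indicator and batch
indicator(s): `−ΔCt ~ treated + batch`. The treatment coefficient *is*
the log2 fold change and its two-sided t-test the reported p. Estimating
on −ΔCt rather than on 2^−ΔCt keeps the model linear in the quantity the
thermocycler actually measures and makes a constant per-batch efficiency
offset an additive nuisance the regression absorbs exactly. Designs in
which treatment is confounded with batch (no batch contains both groups)
are rejected as inestimable. Degenerate zero-residual fits return p = 1
for a zero coefficient (no evidence) and p = 0 otherwise (exact
recovery). Calls use α = 0.05, two-sided, with no multiplicity
correction across the 4 genes x 2 conditions — raw p-values are the
reporting convention for this panel. Calls map to engagement points:
up → +1, down → −1, none → 0.

## Composite scoring

Default weights: concordance acute/chronic 10% each, blood-brain-barrier
penetration 10%, water solubility 10%, TNFα 15%, nitrite 15%, viability
20%, and 1.25% for each of the eight engagement slots — summing to
100%. Pharmacokinetic components take −5/0/+5 (no/unknown/yes).
Contribution = points x weight; subtotals are **cumulative** running
sums in component order (not per-block sums), and the total is the final
running sum. Bounds of the default scheme: +4.6 (everything at its best
band) to −3.6 (concordance floors at 0 since it has no negative bands;
pharmacokinetics and assays floor at −5; engagement at −1 per slot).
Arithmetic uses exact rationals (`fractions.Fraction`, weights parsed
from decimal strings), so printed decimals such as 1.775 are exact
rather than float-rounded. Components without evidence (e.g. engagement
never assayed for a compound) contribute 0 with a warning. Ranking is by
total, ties broken by the co-culture cumulative subtotal, then
alphabetically; the top compound is flagged for in vivo advancement.
The scheme is configuration-driven (YAML), so the same engine serves
other indications with different weights and bands.

## Nested-CV panel classification

Feature engineering: raw per-day measurements, optionally augmented per
series with successive differences and the least-squares slope of value
on day (actual day values 7/14/28 as abscissae, units per day — visit
indices would distort the unevenly spaced sampling). Single-day sets are
raw panels with no augmentation and no feature selection.

Evaluation is nested cross-validation: leave-one-out on the outer level;
within each outer-training set, a stratified k-fold grid search (k = 10,
capped at the minority-class count so every inner fold contains both
classes — this is how degenerate splits are avoided by construction)
maximizes inner ROC AUC over the hyperparameter grid, the winning
pipeline is refit on the full outer-training set and scores the held-out
animal. Standardization and feature selection live inside the pipeline,
so their statistics never see the held-out row. Pooled held-out class-1
probabilities give one AUC per repeat; the procedure is repeated
(default 10x) with fresh fold randomization and classifier
initialization, and the mean AUC is compared against the 0.75 gate.

The classifier is gradient-boosted decision trees (xgboost), pluggable
behind a factory in the config. Default grid: tree depth {2, 3},
learning rate {0.05, 0.1}, trees {50, 200}, plus the F-score selection
percentile {10, 25, 50, 100} when univariate filtering is enabled —
small enough for leave-one-out at n = 26 on a desk machine. Three
selection strategies are available inside the inner loop: top-percentile
by one-way F statistic, above-average-importance filtering from an
extremely-randomized-trees fit, and PCA to a configured variance
fraction; each guarantees at least one surviving feature.

Permutation significance reruns the nested-CV AUC computation on
label-permuted data (one repeat per permutation — the permutation null
needs many draws more than it needs repeat-averaged draws) and reports
p = (1 + #{permuted AUC ≥ observed}) / (1 + n_permutations), the
finite-sample correction that can never return 0.

A caveat worth knowing: pooling leave-one-out scores is *pessimistically
biased* under the null — holding out a class-1 animal lowers the
training prevalence, which systematically deflates that animal's score —
so null pooled AUCs centre somewhat below 0.5 (we measure ≈ 0.45 at
n = 26) and a markedly sub-0.5 AUC on real data is an artefact of the
scheme, not evidence of "anti-signal". The permutation test is immune to
this, since observed and permuted runs share the bias.

## Synthetic data

The generator emulates the statistical structure of each input at the
study's design sizes: DE tables with a known number of filter-passing
genes; concordance tables with named candidates plus uniform decoys;
plates with two experiments of quadruplicate wells and log-normal noise
(right-skewed, non-negative, the natural first model for concentration
data) around planted percent-of-control effects; Ct tables with two
batches, planted log2 effects, a target-gene batch offset and Gaussian
cycle noise (σ = 0.15 cycles, a typical replicate spread); and
longitudinal panels of 15 vehicle + 11 treated animals sampled at days
7/14/28, with per-cytokine baselines spread over 10–200 pg/mL, a
response declining towards the final day, a per-animal random intercept
(SD 0.3 on the log scale) shared across cytokines, residual noise
(SD 0.4) and a multiplicative treated-group shift at the final day.
Each stage draws from an independent substream of the master seed, so
generators never perturb one another and every output is byte-for-byte
reproducible.

What the generator does *not* emulate: absolute assay scales, between-
cytokine correlation beyond the shared animal intercept, heavy-tailed
outliers, plate-position effects, censoring at detection limits, or
attrition. Tests passing on these panels demonstrate that the machinery
is correct and calibrated under its assumed noise model — not that any
particular real-world effect size is detectable.

## Problem sizes used by the test suite

The statistical tests run at deliberately desk-scale sizes chosen as
this package's own defaults: 1000 random small-sample cases for the
exact Mann–Whitney cross-check; parameter recovery on two-batch qPCR
designs of 4 samples per group per batch; one planted-effect panel
(n = 15 + 11, 3 shifted cytokines, 10 repeats) and 32 null panels for
the nested-CV calibration (the pooled-LOO AUC's panel-to-panel spread
is wide, so the chance-level check is on the panel average); 20 null
runs of 20 permutations for the
permutation-calibration check (a single-configuration grid — the
calibration property does not depend on grid size); and 40 seeds for
the end-to-end strong-vs-null compound comparison.

## Known limitations

* The exact Mann–Whitney enumerates C(n, n_a) assignments; beyond a
  pooled n of 16 it switches to the asymptotic approximation rather
  than a faster exact network algorithm.
* Engagement regression assumes homoscedastic Gaussian residuals on the
  −ΔCt scale; undetected wells should be recorded as missing, never as
  an extreme Ct, or the fold-change estimate becomes meaningless.
* The composite scheme's pharmacokinetic points are user-supplied
  literature judgments; the package does not attempt to automate them.
* LOO-pooled AUC bias (above) means the 0.75 gate is conservative.
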