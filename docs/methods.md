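# Methods

This note documents the models and procedures implemented in `prernadx`,
the assumptions behind them, the parameters that matter, and the design
choices made where more than one reasonable option existed.

## Synthetic cohorts

The generator emulates a prediagnostic serum small-RNA-seq case-control
study. Each *individual* receives confounders (sex, age at donation,
blood-donor group BDg — a technical stratum combining handling protocol
and storage time) and, for cases, a histology (NSCLC/SCLC/other), a
stage, and a time to diagnosis drawn uniformly over a 10-year horizon.
Case individuals contribute a second serum sample with probability
`extra_samples_per_case_prob` (default 0.35, matching a cohort in which
~535 case samples come from ~385 individuals); repeated samples share
the individual's confounders and diagnosis but have independent donation
times.

Counts are negative binomial with mean–dispersion parameterization,
variance `m + φ·m²` (default φ = 0.2, a typical bulk-RNA-seq biological
dispersion), sampled as a gamma–Poisson mixture. Per-feature baseline
means are log-uniform over `nb_mean_log_range` (default 10–1000 counts).
The mean of feature *j* in sample *i* is multiplied by

- a log-normal library-size factor (`libsize_log_sd`, default 0.3),
- a log-normal per-individual random effect (default sd 0.2) shared by
  repeated samples — repeated sampling is modeled without asserting a
  specific within-person correlation, which real studies do not report,
- one global log-scale factor per BDg batch (sd 0.3),
- small per-feature random log2 effects for sex (sd 0.15) and a log2
  slope per decade of donation age (sd 0.10), so that matching has real
  structure to remove,
- `2^LFC` for every planted `SignalSpec` whose histology and
  time-to-diagnosis window the case sample matches. Controls never carry
  signal; 'other'-histology cases receive only all-histology signals.

The default feature panel mirrors a post-filter serum RNA composition of
202 miRNAs / 1137 isomiRs / 89 miscRNAs / 380 piRNAs / 119 snoRNAs /
530 tRFs / 790 mRNAs / 59 lncRNAs, scaled down 5× for desk-scale work;
the full composition is one config away.

What the generator does *not* emulate: raw reads and mapping artifacts,
RNA degradation over storage (treated as part of the BDg batch effect),
correlated co-expression modules, and zero-inflation beyond what the NB
produces. Passing tests on these cohorts therefore demonstrate that the
pipeline's logic is correct and calibrated under its assumed generative
model, not that any particular real-data AUC is attainable.

## Preprocessing

The low-count filter keeps features with ≥ `min_reads` (5) counts in
≥ `min_fraction` (0.8) of samples. The published filter sentence is a
double negative; this reading — keep features expressed in at least 80%
of samples — is the only one consistent with retaining thousands of
features, and both knobs are exposed. Filtering is computed on the
modeling (smoker) samples and the resulting panel is applied to the full
cohort so leave-out samples can be scored.

Size factors are median-of-ratios against the geometric-mean reference
restricted to features positive in all samples, rescaled to geometric
mean 1. Normalization is the shifted log `log2(count/s + 1)` — a
deliberate closed-form surrogate for spline-fitted variance-stabilizing
transforms, with the same intent (per-feature sd roughly flat in the
mean, verified by a Monte-Carlo test) and none of the model-fitting
fragility at small n. The normalization step is pluggable if a fitted
VST is preferred.

## Matching

Cases are matched 1:1 to controls exactly on sex × BDg and by age within
a 5-year caliper. Within each stratum the assignment is solved as a
min-cost bipartite assignment (out-of-caliper pairs carry a big-M cost),
which maximizes the number of within-caliper pairs and, among those,
minimizes total age distance. An optimal assignment was chosen over
nearest-age greedy after greedy was measured to lose matches on ~7% of
random small instances and to exceed the optimal total distance many
times over; the exact solver is equally deterministic (inputs are sorted
by age and sample id) and matches a brute-force enumeration on all
small instances in the test suite. Unmatchable cases are reported, never
dropped. Matching is done once on the full modeling set; window models
subset the matched pairs afterwards.

## Time windows

Windows are half-open `[start, start+width)` so that sliding windows at
step 1 partition the horizon cleanly; a case exactly at the right edge
is excluded. Presets: sliding widths 2/3/4 years stepped by 1 over a
10-year horizon, fixed windows 0–2/0–5/0–8, and the full window. A
window keeps the cases inside it (optionally restricted to one
histology) plus **all** controls, which are cancer-free over the whole
horizon and hence valid comparators for every window.

## Repeated matched ML workflow

Matched pairs move between train and test as whole units, preserving
1:1 class balance and confounder matching on both sides. The default
split unit is the *individual*: pairs sharing any individual are merged
(union-find) so repeated samples never straddle the split;
`unit="sample"` mirrors analyses that accept that risk. Repeat *r* uses
seed `base_seed + r`, so the whole workflow is a pure function of
(cohort, config, base seed) — verified byte-for-byte.

Backends: L1 logistic regression (liblinear), elastic-net logistic
regression (saga), sparse group lasso, random forest, and XGBoost.
Sparse group lasso — logistic loss plus
`λ[α‖β‖₁ + (1−α)Σ_g √p_g ‖β_g‖₂]` with RNA classes as groups — is
implemented by proximal gradient descent (ISTA with backtracking,
objective tolerance 1e-6, ≤ 5000 iterations) on standardized features
with an unpenalized intercept, since no grouped-penalty logistic solver
is part of the dependency set. Importances are |coefficient| for linear
models and split gain (XGBoost) or impurity decrease (forest) for
trees; they are comparable only within a backend, so cross-model
statements use selection frequency.

Tuning is grid search maximizing mean AUC over stratified seeded 5-fold
CV on the training split; ties go to the first grid point; a
single-point grid fits directly. Two grid families exist: `default`
(30 log-spaced λ for lasso/elastic-net with α ∈ {0.2, 0.5, 0.8}, XGBoost
depth {2,3,4} × learning rate {0.05, 0.1} at 200 rounds, forest with
√p and p/5 feature subsampling at 500 trees) and `fast`, a compact
version used by the regression suite, demo configs, and the acceptance
runner so that full repeated workflows on ~240-sample, 600-feature
cohorts finish in seconds to minutes on one CPU. Problem sizes in the
shipped tests (120+120 samples, 600 features, 5 repeats, 24 sliding
windows) were chosen as the smallest at which the calibration and
recovery properties are comfortably estimable.

Feature selection runs on the training split only, with one deliberate
exception: lasso pooling is *defined* as the union of nonzero lasso
coefficients across the five repeats' training fits, followed by
retraining restricted to the pool — a cross-repeat construction with a
known optimistic bias that is part of the procedure being reproduced,
and is logged as such. Univariate screening fits one logistic regression
per feature (Newton), takes the Wald p-value on the slope, falls back to
a likelihood-ratio test under complete separation (flagged), assigns
p = 1 to constant features by convention, and keeps q ≤ 0.05 after
Benjamini–Hochberg.

Windows capturing fewer than `min_cases` matched cases (default 20; the
desk-scale sliding-window runs use 10) are skipped with a warning rather
than failing the run.

## Evaluation and risk

AUC is the tie-corrected Mann–Whitney concordance; the ROC sweep
collapses tied scores, so the trapezoidal area equals the AUC (both
facts are property-tested against a brute-force pairwise oracle).
Accuracy/sensitivity/specificity use `positive = score ≥ threshold`.
Across repeats the 95% CI is `mean ± t_{n−1,0.975}·sd/√n`; with n = 5
repeats the t quantile is materially wider than the normal one, which is
why the t construction was chosen.

The operating threshold of a final model maximizes Youden's J
(`sn + sp − 1`; the conventional default of cutpoint-selection tools,
with accuracy and F1 available) over out-of-fold CV scores from the
training split; candidates are midpoints between adjacent distinct
scores, ties break toward the lower threshold, and the threshold is
frozen before any test or leave-out sample is scored.

Frequent features are ranked by selection frequency across repeats,
then mean importance, then feature id; the defaults (top 25, selected in
≥ 3 of 5 repeats) correspond to compact panels of ~19–25 RNAs per
histology. The compiled panel is refit on an 80/20 matched split and
evaluated twice: on the held-out test set alone and with the leave-out
set (non-smokers plus smokers never used in matching) appended. Any
intersection between leave-out and training ids is a hard error.

Relative risk uses the Wald log-RR interval
`exp(ln RR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))` and a two-sided z
test on ln RR; tables with a zero cell get a +0.5 continuity correction
in every cell and are flagged. The implementation is cross-checked
against statsmodels' 2×2 machinery on random tables.

## Enrichment

Over-representation is the plain one-sided hypergeometric tail
`P(X ≥ k)` with BH adjustment across pathways, on a universe defaulting
to all genes in the supplied target map plus all mRNA features
(overridable). Published analyses of this kind often use bias-aware
enrichment models that weight genes by length or coverage; those need
per-gene covariates that a count matrix does not carry, so the plain
ORA is used and results should be read as exploratory — they are
universe-sensitive by construction. miRNA/isomiR→gene mapping keeps
predictions with score strictly greater than 60, the conventional
confidence bound for such prediction databases. No pathway or target
content is bundled (licensing); inputs are user-supplied GMT and
three-column TSV files.

## Orchestration

`run_all` executes simulate/load → smoker restriction → preprocess →
match → workflow → frequent-feature/risk stage → report, echoing every
defaulted parameter, all seeds, and a config hash into `run_log.json`
(one structured event per stage, including skipped-window warnings).
Outputs are a pure function of config bytes; re-running a config
reproduces every artifact byte-identically. Stages are re-executed on
each run — fitted models are not serialized, so resumability is at the
granularity of a whole run (identified by its config hash) rather than
per stage.

## Known limitations

- The shifted-log transform under-stabilizes very-low-count features
  relative to a fitted VST.
- The synthetic generator's independence assumptions (no co-expression,
  NB margins) make planted signals easier to find than real biomarkers;
  calibration results transfer, absolute AUCs do not.
- Lasso pooling across repeats leaks selection information into test
  splits by construction (see above).
- The exact split seeds of any given published analysis are not
  recoverable; only the procedure, not the realized splits, is
  reproducible.
- The relative-risk CI is unconditional Wald; exact or score intervals
  would behave better at very small cell counts than the continuity
  correction used here.
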