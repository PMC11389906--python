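# Methods

## Model and procedure

The package targets case-control discrimination in a symptomatic,
low-prevalence cohort: serum samples with one of 16 control diagnosis
classes (15 benign/confounding conditions from a symptomatic referral
cohort plus a screening-derived healthy class) or PDAC (coded 1
throughout), measured on a multiplex protein panel reported on the NPX
log2 scale plus five ELISA markers handled on a log scale in memory.

### Discovery/validation split

Samples are allocated 2/3 discovery, 1/3 validation, stratified on age
bin × diabetes status × case/control label × diagnosis class, plus
tumour stage for cases. Age bins are (18,28], (28,38], (38,48],
(48,58], (58,68], (68,78], [79,∞); ages below 18 are rejected at load.
Where a stratum's 2/3 target is fractional, the rounding direction is
randomized by seed, so neither arm is systematically inflated; the
discovery count never deviates from `round(2n/3)` by more than one.
Screening-source controls can instead carry a fixed external
assignment, mirroring reuse of a split inherited from an earlier
study. The validation arm is quarantined structurally: every training
entry point receives only the discovery subset produced by the split
object, and nothing downstream reads validation labels before the
evaluation stage.

### Bridging normalization

Two measurement batches are aligned with shared bridge samples
measured in both. For each assay the correction subtracts from the new
batch the median over bridge pairs of (new − reference); afterwards
the per-assay median bridge difference is exactly zero. The median was
chosen over the mean for robustness to single aberrant bridge
measurements; the procedure is idempotent and shift-equivariant, and
refuses to run on fewer than two pairs.

### Firth logistic regression

All univariate association statistics use Firth's bias-reduced
logistic regression, maximizing l(β) + ½·log det I(β) (the Jeffreys
prior penalty). The solver is a modified-score Newton iteration with
the hat-value-adjusted response y − π + h(½ − π), step-halving on any
decrease of the penalized log-likelihood, tolerance 1e-8 on the
largest score component, and a 50-iteration cap with explicit
non-convergence flagging. For a single binary covariate the estimate
coincides with the Haldane–Anscombe add-½ cross-product odds ratio,
which the tests use as an exact oracle. Confidence intervals profile
the penalized log-likelihood: the bounds solve
2·[l*(β̂) − l*_profile(β)] = χ²₁(0.95), located by outward bracketing
from the estimate and Brent root finding, with unbracketable sides
reported as infinite. Per-term p-values are penalized likelihood-ratio
tests against the model with that term fixed at zero, with the penalty
evaluated on the full design.

### Base learners

One classifier per control class: that class's discovery controls
against all discovery PDAC cases. Training is leave-one-out
cross-validation in which *everything* is recomputed per fold —
standardization statistics from the fold's training rows, imbalance
resampling of the training rows only, RFE ranking on the resampled
fold — so the held-out row cannot influence feature selection.
Candidate subset sizes default to {1..10, 15, 20, 30, 45, 60, p}; the
size with the best pooled out-of-fold AUC wins (pooling the held-out
probabilities into a single AUC is the standard resolution when folds
hold a single row; ties go to the smaller size). The final model is
refit on the full training subset at the winning size, unpenalized;
under complete separation it falls back to Firth penalization (or to
the ridge-stabilized fit when duplicated resampled rows make the
design rank-deficient).

RFE drops the feature with the smallest absolute standardized
coefficient from a ridge-stabilized logistic fit (L2 = 1e-4, intercept
unpenalized — the ridge only guards against separation in tiny folds)
and refits until one feature remains. Numerical coefficient ties are
broken lexicographically: the alphabetically later name is dropped, so
duplicated columns resolve deterministically.

### Resampling

Three in-fold imbalance corrections, all returning exactly balanced
classes: random oversampling of the minority with replacement, random
undersampling of the majority without replacement, and SMOTE (synthetic
points uniform on the segment to one of the k = 5 nearest minority
neighbours, neighbour search on standardized features, k capped at
minority−1, degradation to plain oversampling with a warning when only
one minority row exists). Oversampling is the pipeline default.

### Stacking

The meta-learner is a logistic regression on the logits of the base
learners' probabilities, clipped to [1e-6, 1−1e-6] — clipping keeps the
meta-design finite when a base learner saturates, and working on the
logit scale linearizes the meta-problem. Two meta-input conventions are
implemented and recorded in provenance: `insample` (base learners
applied to the whole discovery set; the default, matching how base
learner performance is reported) and `oof` (each learner's own
training rows contribute their leave-one-out probabilities; the
leakage-safe alternative). Constant meta-columns are dropped with a
warning; separation triggers a Firth meta-fit. Recursive base-learner
elimination greedily removes the learner whose removal most improves a
validation-free metric — pooled stratified 5-fold CV AUC at the meta
level — and returns the full trace; the validation arm is never
consulted. A reduced signature re-runs the entire diagnosis-specific
protocol restricted to a named candidate list (default: CA19-9, VWF,
CPE, CTSV, CEACAM1, CD160, diabetes, age).

### Comparators

The whole-cohort RFE-glm baseline reuses the base-learner machinery on
all discovery controls at once (one model, no stacking). Random-forest
and gradient-boosted-tree baselines delegate fitting to scikit-learn
and tune by random search (declared grids, default 1000 draws; the
search trace is retained) scored by pooled cross-validated AUC with
in-fold resampling; LOOCV is honoured by default with a K-fold
downgrade available for speed. All comparators consume exactly the
same candidate features and split as the ensemble.

### Evaluation

AUC is the tie-corrected Mann–Whitney statistic. Operating points fix
specificity at 0.90 with the threshold restricted to observed score
values (smallest observed value whose specificity reaches the target;
no interpolation — reproducible and conservative). When no observed
value attains the target, sensitivity is 0 and PPV undefined.
Uncertainty comes from stratified bootstrap (cases and controls
resampled separately; percentile intervals; default 2000 resamples)
with the operating threshold re-derived on every resample, so
threshold-selection variability is inside the interval. Resamples on
which a metric is undefined are redrawn with the count logged; a
metric undefined on essentially every resample yields no interval
rather than an error. Paired model comparisons standardize the
observed metric difference by the bootstrap SD of the difference and
take the one-sided normal tail (default 10000 resamples), the
convention of the pROC bootstrap test; the same machinery serves AUC
and sensitivity-at-90%-specificity. Symptom-subset and QCancer
analyses apply an already-trained model with no refitting,
concatenating discovery and validation probabilities before
subsetting, and report the Pearson correlation (t-test p) between the
QCancer score and the model's log-odds.

### Feature importance

Model-agnostic permutation importance: the mean AUC drop over 20
independent permutations of one feature's column, with features a
learner never selected assigned exactly 0 without computation, and a
per-feature random stream keyed by the feature name so the result is
invariant to feature order. Within each learner importances are scaled
to max 100; the cross-learner aggregate is the plain mean with zeros
included, sorted descending with lexicographic tie-breaks.

## Synthetic cohort generator

The generator is the package's study bed: patient-level data of this
kind are consented and not public, so all structural claims are
exercised on simulated cohorts with known ground truth. Marker values
are additive on the NPX log2 scale — per-marker Gaussian baseline +
(marker, group) shift from the effect map + per-batch assay offset +
Gaussian noise (SD 1.0) — so planted effects have exact
mean-difference semantics. Defaults reproduce the published cohort's
marginal structure as *generation targets*: 421 symptomatic controls
across 15 benign classes plus 72 screening-source healthy controls
(all female, batch 2), 46 cases staged 4/15/10/16/1 (I/II/III/IV/
unknown); case/control age means 69.7/57.4, male fractions 31/46 and
180/421, diabetes 10/46 and 75/421, ethnicity category frequencies per
the published table. Twelve binary symptom flags exist only for
symptomatic-source samples, with case/control prevalences chosen to
match the reported association directions (jaundice and weight loss
enriched in cases; reflux and bloating in benign controls) — the
published per-symptom counts are not available in text form, so the
exact prevalences are package defaults, not reproduced values. A
QCancer-style percent-risk score is simulated through a logistic link
on age, sex, case status and red-flag symptoms (so case scores
stochastically dominate), available for a configurable fraction of
symptomatic samples (default 0.1, reflecting how sparsely such scores
are recorded at referral). Batch structure: two batches, per-assay offsets N(0, 0.3),
16 bridge samples re-measured under both offsets with independent
noise. ELISA markers are simulated on the log scale and exponentiated
on disk with a declared transform flag. Missing marker values default
to none; a missingness rate option exists.

What the generator does **not** emulate: assay chemistry and QC
(limits of detection, plate effects beyond a per-batch shift),
correlated marker blocks (markers are independent given group), dates
and centres, and the realized (slightly uneven) case split of the
original study. Passing tests therefore demonstrate that the
*protocol* behaves correctly under the assumed data-generating
process, not that any particular marker panel generalizes to real
patients.

## Problem sizes in the test and acceptance runs

The shipped tests run the protocol at reduced but structurally
faithful sizes, chosen as the package's own defaults for routine
verification: base-learner studies use a median-size diagnosis class
(≈20 controls) against the 24 discovery cases with 4–8 markers and a
{1,2,3}-size RFE grid; the 16-class pipeline check uses 9 controls per
class, 16 cases and 12 markers; Monte-Carlo studies use 100 seeds for
recovery/calibration counts, 25 seeds for stack-vs-single comparisons,
and 200 replicates at n = 100/100 with 2000 resamples for bootstrap
coverage.

## Numerical choices and edge cases

* Logistic solvers: dense Newton with step halving; linear predictors
  clipped at ±30; `solve` falls back to least squares on singular
  Hessians.
* Youden cutoff: candidate thresholds are midpoints between adjacent
  observed scores (positive call at score ≥ threshold); among J ties
  the lowest threshold is returned; a constant score vector gives
  J = 0.
* Degenerate folds (single-class after held-out removal) contribute
  probability 0.5.
* Stage counts must sum to the case count; effect-map keys must
  reference declared markers and groups; probabilities are validated
  into [0,1].
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; per-fold and per-learner streams are
  derived arithmetically from the caller's seed, so every artefact is
  bit-reproducible.

## Known limitations

* The pooled-LOOCV AUC of a base learner is a noisy, slightly biased
  estimator (single-row folds share almost all training data; with
  strong class imbalance the pooled score drifts below 0.5 on null
  data, and selecting the best subset size drifts it upward). The
  score-level stratified bootstrap treats the out-of-fold scores as
  independent and therefore somewhat understates the variance of this
  estimator; its empirical 95% coverage of the null AUC sits below
  nominal in our calibration runs. This is a property of bootstrapping
  cross-validated scores, not of the resampling modes it is used to
  guard.
* Profile CIs assume a unimodal penalized likelihood (guaranteed for
  logistic models with full-rank design).
* The tree comparators are baselines, deliberately delegated to
  scikit-learn; their hyperparameter grids are declared configuration,
  not reproduced from any external source.
* One-hot handling of multi-category ethnicity is exposed as both
  one-vs-rest recoding and full dummy coding; analyses here default to
  one-vs-rest, which is the form that reproduces from printed
  contingency tables.
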