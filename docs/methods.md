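# Methods

This note documents the models, defaults and numerical choices behind
`vipnomics`, and what the synthetic-data experiments do and do not show.

## Phenotype model

TNS©-PV is a non-negative clinician-assigned neuropathy severity score
assessed repeatedly over the 2–3 year treatment. A single score is *low*
below 3, *high* above 8, *medium* otherwise. The overall phenotype is
**HN** if any visit is high — severe neuropathy once observed marks lasting
susceptibility, even if later scores improve after dose modification — and
**LN** only if every visit is low. Everything in between is MEDIUM and is
excluded from model building: the classifiers are binary by design and
deliberately silent about intermediate phenotypes (a known limitation of the
decision rule below).

Both thresholds are strict inequalities. The phrase "a score of 8 or higher"
occurs once in clinical descriptions of this scheme while "greater than 8"
is the operative rule; we follow the strict reading (8 is medium) and expose
both cutoffs as arguments of `score_to_intensity` / `classify_overall`.

## Synthetic cohort generator

The generator (`vipnomics.synthetic`) emulates the cohort structure the
analysis assumes, not raw LC-MS data:

- **Cohort**: 24 HN / 12 LN patients by default (2:1 unbalanced), optional
  MEDIUM patients that the phenotyping stage must exclude; three time points.
- **Intensities**: normal on the log10 scale — a per-feature baseline
  N(6, 0.8) shared across time points, unit within-feature noise, plus a
  global per-time-point offset (`timepoint_shift`, default 1.0 ≙ one decade
  per time point). The shared baseline plus offset reproduces both the
  clustering of profiles by time point and comparable feature scales across
  time points. Stored values are raw intensities `10^z`.
- **Signal**: `n_informative_per_timepoint` (default 5) features per time
  point carry an HN−LN group-mean difference of `effect_size` (Cohen's d on
  the log scale, default 2.0) with alternating sign. The per-time-point
  informative sets are disjoint by default — the structure behind
  time-point-specific biomarker panels. With `shared_informative=True` the
  same set carries signal at every time point (fresh noise draws), the
  regime in which the longitudinal coupling parameter becomes positive.
- **Missingness**: a fraction `missing_rate` (default 0.2) of metabolite
  cells per matrix is masked; by default the lowest intensities are masked
  first (below-threshold, the LC-MS limit-of-detection mechanism), with a
  purely random alternative. The drug-concentration column is always
  observed (it comes from a separate targeted assay).
- **Drug column**: a `vincristine_conc` column, log-normal and independent
  of phenotype; a correct selection procedure must not pick it.
- **Trajectories**: four visits (the three profiling time points plus a
  catch-all late visit). LN scores are uniform 0–2 throughout; HN patients
  get a first-high visit drawn with probabilities 1:8:8:7 across the four
  visits, so high scores appear mostly at later visits; MEDIUM patients peak
  in (3, 8].

What the generator does **not** emulate: batch effects, m/z or retention
drift, heteroscedastic or correlated features, patient-level random effects
across time points, and intensity-dependent variance. Passing tests
therefore show the pipeline's operations are correct and recover planted
structure — not that the real-data effect sizes or selected panel sizes are
reproducible; those depend on the study's LC-MS measurements.

## Preprocessing

- **Presence filter**: a feature is kept iff observed in ≥ `min_fraction`
  (default 0.75) of HN samples or of LN samples. Groups are the overall
  phenotypes, matching the labels used everywhere downstream. Idempotent.
- **log10**: metabolite intensities span decades; all modelling happens on
  the log scale. (Whether to log-transform is exposed as a pipeline flag.)
- **KNN imputation**: feature-wise. A missing cell (sample i, feature j) is
  the unweighted mean over the k = 10 features nearest to j — by
  root-mean-square difference over mutually observed samples — that are
  observed at sample i; fewer than k usable neighbours falls back to the
  feature's observed mean. RMS (rather than raw Euclidean) distance keeps
  feature pairs with different overlap sizes comparable. Observed cells are
  never altered.
- **Standardization**: per-feature mean 0 / SD 1 (ddof = 1); zero-variance
  features get scale 1 with a warning. The fitted center/scale is stored in
  the model file and re-applied verbatim to new samples. Inside every CV
  fold, standardization is refitted on the training fold only.

## Clustering

Ward.D2: scipy's `ward` linkage on the raw observation matrix, i.e. Ward's
criterion with the squared-distance Lance–Williams update on Euclidean
distances. Cross-time-point stacking uses the intersection of features
surviving the presence filter at every time point, imputed jointly after
stacking (this guarantees a common feature space). Profiles enter on the
log10 scale without standardization, so the global per-time-point offset
dominates the geometry, which is exactly the claim the purity statistic
quantifies: purity of an n-cluster flat cut = Σ per-cluster majority count /
n samples. The dendrogram exports to Newick with branch lengths derived from
merge heights (root-to-leaf distance equals tree height).

## Longitudinal coupling (β)

The coupled classifier Y = f(X̃_t₁ + β X̃_t₂) uses the same linear SVC
(cost 0.25) as the rest of the pipeline, with both matrices standardized on
a common feature set. The objective E(β) is the mean misclassification error
of repeated stratified 5-fold CV on the combined matrix, with **one fold
assignment reused for every β** so the curve is comparable across the grid.
β = 0 reduces exactly to the single-time-point classifier on t₁.

Estimation is derivative-free: a grid scan over [−2, 2] step 0.1, plus
golden-section refinement of the best bracket, plus a local grid descent and
refinement from each initial guess (default −1, 0, 1) to expose
multi-modality. Because E is a step function of a finite prediction count,
differences below a few prediction slots are fold noise; two β values whose
errors differ by ≤ `error_tol` (default 3 / n_cv_predictions) are treated as
equivalent and the smaller |β| wins (parsimony: report no coupling unless
coupling measurably reduces error). Without this rule, single-prediction
error quanta pin the descent at plateau edges.

Identifiability caveat, visible in simulation: when the t₁ signal alone does
*not* reach its CV error floor, the coupled model can genuinely reduce error
at β ≠ 0 by importing t₂'s own (disjoint-feature) signal, and the minimizer
sits away from zero. The "β ≈ 0 for disjoint panels" behaviour is the
regime where the single-time-point model is already near its error floor —
as with a day-8 panel whose AUROC is ≈ 0.97. The β simulations therefore use
effect size 3 with 10 informative features per time point (error-floor
regime); the shared-informative simulations use effect size 1.2 so that the
coupling gain near β = 1 registers above the floor. Under permuted labels
the error curve has no minimum below chance level, but its min–max spread
across the grid (≈ 0.15–0.2 at n = 36) is dominated by per-β
data-realization variance and does not shrink with more CV repeats.

## Feature selection (SVM-RFE)

Within every resample of a repeated stratified 5-fold × 20 split: fit the
SVC (cost 0.25) on the standardized training fold, rank features by absolute
weight, retain the top-s features for the next candidate size (re-ranking at
each retained size, i.e. truly recursive), and record held-out AUROC (from
decision values), sensitivity and specificity at each size. Candidate sizes
are 1–50 plus always the full feature set (the full set can win). The chosen
size maximizes mean held-out AUROC, ties toward the smaller size; the
reported feature list replays the elimination trajectory on the full
standardized data.

The ensemble repeats this `n_iter` times (reference depth 100) with
counter-derived seeds; the winner has the highest AUROC at 1e-4 resolution,
ties broken by the lowest specificity SD, then by iteration order.
`bootstrap_final_fit` reports the complementary metric convention:
out-of-bag AUROC/sensitivity/specificity over 25 bootstrap resamples of the
selected panel (resamples missing a class in either part are redrawn).

A note on "recovery": with 36 samples and effect size 2, a single strong
planted feature often separates the cohort nearly perfectly, so free model
selection legitimately prefers subset sizes 1–3. Recovery of the planted
set is therefore assessed at the planted size (the ranking quality of RFE),
while free selection is checked for never admitting noise features.

## Final model and decision threshold

Cost is tuned over {0.25·2^k, k = 0..9} (ten doublings, the tuning-length-10
convention) by repeated stratified 5-fold × 20 CV with mean held-out AUROC
as the metric; ties go to the smallest cost. Probabilities come from Platt
sigmoid calibration — P(HN | d) = 1/(1 + exp(A·d + B)) — fitted by BFGS with
prior-corrected targets on the **pooled** cross-validated decision values at
the winning cost (each sample contributes one held-out decision per repeat).
The final SVC is refit on all data at the winning cost; the model file
stores features, center/scale, weights, intercept, cost, (A, B), threshold
and CV AUROC as versioned JSON.

Because the cohort is 2:1 unbalanced, the probability cutoff is not 0.5:
the scan over [0.5, 1] step 0.01 picks the cutoff minimizing
√((1−sens)² + (1−spec)²) on the pooled CV predictions (Youden's J is
reported alongside); ties go to the lowest cutoff; a sample is called HN
when its probability strictly exceeds the cutoff. Pooling across repeats
(rather than averaging per repeat) is the implemented convention.

The two-time-point rule flags "consider dose adjustment" only when the
day-8 and month-6 probabilities both strictly exceed their thresholds —
one consistent signal across an early and a late sample, reflecting that
the models cannot see MEDIUM phenotypes and should be conservative.

## Evaluation

Positive class is HN throughout (the only convention under which predictive
values and prevalence are mutually consistent in the cross-validated metric
tables). From the pooled 2×2 counts: accuracy with exact Clopper–Pearson
95% CI; NIR = majority-class fraction with a one-sided exact binomial test
of accuracy > NIR (n = pooled CV prediction count); Cohen's kappa; McNemar's
chi-square with continuity correction; sensitivity/specificity, PPV/NPV,
prevalence, detection rate/prevalence, balanced accuracy. AUROC is the
trapezoid integral of the ROC curve over all cut points and equals the
normalized Mann–Whitney concordance (ties ½) — asserted against a
pair-counting oracle. A percentile bootstrap CI is provided for AUROC.

## Problem sizes and determinism

Simulation-backed tests and the acceptance script run scaled-down study
conditions chosen once: cohorts of 36 patients; 100 features for β
estimation, 500 for RFE recovery, 120–300 for clustering and end-to-end
runs; CV at 5 folds × 10–20 repeats; RFE ensembles of 1–2 iterations in
end-to-end runs. Every stage derives its seed from one master seed via
`SeedSequence` spawn keys; a rerun with the same inputs and seed reproduces
all artifacts byte-for-byte (JSON with sorted keys, deterministic float
repr).

## Known limitations

- Binary HN/LN only; MEDIUM patients are excluded, so the decision rule
  must not be read as a full triage instrument.
- The cross-validated metrics are optimistically biased at the ensemble
  winner (selection optimism); the null-control tests quantify the chance
  level but no external test set exists in this design.
- The modified-KNN variant (feature-wise, RMS distance, mean of k = 10
  neighbours) is one documented reading of a loosely specified step;
  k, the distance and the orientation are configurable.
- β is a scalar per time-point pair, per the coupled model's notation; a
  per-feature coupling is out of scope.
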