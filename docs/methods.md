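# Methods

## The problem being modeled

A clinical prediction model is trained in one context (an era, a feature
set, a data volume, a patient population) and used in another. `icushift`
quantifies the resulting performance loss on two critical-care tasks —
acute kidney injury (AKI) within 7 days of ICU admission, and ICU
readmission within seven time windows — by generating synthetic cohorts in
which each context shift has a known, adjustable magnitude, then measuring
held-out AUROC under five split regimes: a random baseline, a temporal
(EMR-epoch) split, a feature-set change with and without transfer learning,
training-set sub-sampling, and an ethnicity-based population transport.

Because the cohorts are synthetic, every result is a statement about the
pipeline's behavior under *known* shift mechanisms, not about any real
patient population. The value of the package is the controlled testbed:
effects have ground truth, calibration is checkable, and the whole study
runs on a laptop in minutes.

## The generative model

Each stay i carries a latent severity vector z_i ∈ R^8, standard normal.
An augmented vector x_i appends two interaction terms, z0·z1 and z6²−1.
The ground-truth AKI risk is

    p_i = logistic( β·x_i + δ·1[epoch=post]·(γ·x_i)
                    + η·1[ethnicity≠White]·(κ·x_i) + b0 )

with fixed coefficient vectors β, γ, κ (see `cohort.py`). Key properties:

* **Drift as coefficient rotation.** γ is chosen nearly orthogonal to β, so
  increasing the drift magnitude δ monotonically decorrelates the pre- and
  post-epoch regimes. A pure covariate mean shift would be absorbed by
  feature normalization and make the drift scenario trivially null; a
  rotation cannot be normalized away, yet retraining on post-epoch data
  recovers performance — the phenomenology a drift study needs.
* **Population effect.** η applies the same construction through κ for
  non-White patients.
* **Planted urine signal.** Component z7 has a large weight in β but
  appears *only* in the urine-output channel (first-24 h rate
  0.6 + 0.9·logistic(−1.2·z7) mL/kg/h, floored above the oliguria
  threshold). Removing the urine feature group therefore costs real AUROC,
  which is what the change-of-features scenario measures.
* **Planted nonlinearity.** The interaction terms enter the risk but only
  their factors (z0, z1, z6) are observable in the channels, so a deep
  model has a genuine capacity advantage over a linear or very narrow one.
* **Calibrated intercepts.** b0 is solved per cohort (Brent's method) so
  the mean risk equals the configured AKI rate; the empirical stage mix
  then converges to the configured mix. The readmission flag uses the same
  construction with its own coefficient vector θ (plus δ/η rotations), and
  the readmission gap is drawn from a two-component log-normal mixture
  (early bounce-back: median 36 h, σ=0.8, weight 0.35; late: median 400 h,
  σ=0.9) with the any-readmission probability solved so that the marginal
  72-hour rate equals `readmission_rate_72h`.

Crossover-epoch stays draw their risk regime by coin flip between pre and
post; they exist to be excluded by the drift split, mirroring a record
system's migration phase.

### Stage-consistent trajectories

`trajectory_from_stage` inverts the KDIGO rules with explicit margins so
staging the generated series recovers the intended stage for 100 % of
stays — by construction, not by chance:

* Stage 0 creatinine stays within ±0.07 mg/dL of a baseline in
  [0.65, 1.05] mg/dL: the worst-case ratio (1.31×) and 48-h delta
  (0.14 mg/dL) sit well inside the stage-1 thresholds (1.5×, 0.3 mg/dL).
* A creatinine-arm injury ramps after hour 30 to a peak drawn strictly
  inside its stage band (stage 1: 1.62–1.85×, clipped below 1.95×;
  stage 2: 2.15–2.85×, clipped below 2.95×; stage 3: 3.3–3.9×), relative
  to the *observed* first-24 h minimum, which is exactly the labeler's
  baseline.
* A urine-arm injury (chosen with probability ½ when urine is available)
  inserts an oliguric episode starting between hours 26 and 80 whose rate
  and duration sit inside one stage band with ≥ 1.2 h margin against the
  ±20 % charting jitter (stage 1: 0.35–0.45 mL/kg/h for 7.5–10 h; stage 2:
  0.33–0.45 for 13.5–20 h; stage 3: 0.12–0.25 for 26–40 h).
* All injuries begin after hour 24, so generated AKI is never excluded as
  admission AKI, and every stay charts creatinine near hour 2, so the
  baseline is always computable.

### Observation schedule

Creatinine every 12 h over 7 days, urine hourly over 7 days, vitals hourly
over the first 48 h, labs daily over 7 days, all with ±20 % cadence jitter.
Vitals stop at 48 h because every downstream consumer reads the first 24 h;
extending them would quintuple the observation table without changing any
result. Urine charting jitter never exceeds the 2-hour gap tolerance of the
staging rules.

## KDIGO staging choices

* **Baseline creatinine** = minimum value in the first 24 h of the stay.
  The cohort excludes admission AKI, so early values approximate the
  pre-injury baseline; no universal definition exists for ICU data.
* **Urine rates** are interval-averaged: each charted value (mL/h) covers
  the interval ending at its timestamp, the first value covering from
  hour 0. Gaps > 2 h break a sustained span. The consensus rules are
  silent on irregular sampling; hourly charting with small gaps is the
  modal ICU pattern.
* **Arbitration.** Stay stage = max over arms; onset = earliest time that
  stage's condition holds; arm ties at equal stage break to earlier onset,
  exact onset ties report the creatinine criterion; within the creatinine
  arm, ratio is preferred over absolute over delta at identical times.
* **Window.** Evaluation is censored at 168 h from admission; truncating
  later observations never changes a result (tested).
* Renal replacement therapy (an alternative stage-3 trigger) is outside the
  staging logic: the schema carries no RRT channel. Extension point.

## Feature matrix

83 columns in a fixed, documented order: 4 demographics (age, male sex,
weight, White ethnicity), 10 comorbidity flags, 13 vitals/labs channels ×
4 summaries (mean/min/max/last over the first 24 h), 3 urine features
(mean rate, min rate, hours below 0.5 mL/kg/h — droppable as a group),
minimum eGFR, and 13 creatinine-derived features. eGFR is MDRD-4
(175·SCr^−1.154·age^−0.203·0.742[female]·1.212[Black]), the standard
creatinine-based estimate of the era the schema emulates; minimum eGFR is
computed from the maximum 24-h creatinine. The 24-hour feature window is a
design choice: features must precede most onsets for the 7-day prediction
target to be meaningful.

Missing summaries are imputed with training-set medians and features are
standardized with training-set mean/sd; both parameter sets are refit on
exactly the rows flagged train, and raw summaries never depend on the
flagging (tested by perturbing test rows).

## Models

The MLP is implemented in NumPy because transfer learning by layer freezing
needs per-layer control of updates: frozen hidden layers must be bitwise
unchanged after fine-tuning. Architecture: ReLU hidden layers, softmax
output, class-weighted cross-entropy (keeping AUROC estimation at natural
prevalence, instead of resampling), Adam (lr 1e-3–3e-3, batch 128–256), L2
1e-4, early stopping on a stratified 10 % validation split with patience.
All randomness (init, batching, splits, folds) derives from the spec seed.

* The default AKI architecture is a 15-hidden-layer tapering stack
  (96…8); the depth is a fixed property of the predictor under study, the
  widths and optimizer settings are fixed here. Scenario sweeps default to
  a compact (24, 12) spec — at the cohort sizes this package runs, the deep
  and compact models reach similar AUROC and the compact one trains an
  order of magnitude faster; the 15-layer model remains available and
  smoke-tested.
* The primary AKI task is binary (any stage vs. none), since each
  experiment reports a single AUROC; 4-class staging is available through
  `predict_proba_full`.
* Transfer: the input layer is widened (old-feature weights copied,
  new-feature weights zero — so zero fine-tune epochs reproduce the old
  model exactly, including its per-feature normalization), hidden layers
  2…depth−1 freeze by default (the last hidden layer when depth is 2), and
  the input and output layers adapt.
* Readmission uses one independent binary classifier per window, same
  family as the AKI model.

## Scenarios and their numerical conventions

* Baseline: label-stratified 80/20 split per seed.
* Drift: all pre-epoch stays train, all post-epoch test, crossover
  excluded; seeds vary only model initialization. Test-set size is
  reported rather than size-matched (the raw mode is the default; the
  baseline's n is carried in every result row).
* Scarcity: a stratified random fraction trains, the full remainder tests,
  so test size varies with the fraction and is recorded per result.
* Feature change: per seed, one fixed 80/20 split; the reference model
  trains without urine on the full training side; three arms (without
  urine, with urine from scratch, with urine via transfer from the
  reference) train on each grid fraction and score on the common test set.
  The crossover fraction is the smallest grid fraction whose mean AUROC
  reaches the reference's full-data AUROC.
* Population: train on White stays, test on Black and on Latinx stays
  separately. With `holdout_reference=True` the trainer holds out 20 % of
  White stays and also scores them, isolating the population effect from
  training-size effects — this is the gap definition the dose-response
  check uses.
* Confounding tables report the percentage of each column level within
  each row partition and within the whole cohort; levels omitted from the
  columns (the crossover epoch) make rows sum to less than 100 %.
* Replicated scenarios report mean ± sd over ≥ 3 seeds; the default
  fraction grid is 0.05…1.00 in steps of 0.05, and coarser grids are used
  where a sweep's shape, not its resolution, is under test.

AUROC is the Mann–Whitney concordance with 0.5 credit for ties, computed
from average ranks; it errors (never defaults to 0.5) when a class is
absent. An exhaustive pair-counting oracle agrees to 1e-12 in the tests.

## Problem sizes

Mixture-convergence checks run at n = 20,000 stays (±2 percentage points);
null-shift calibration at n = 8,000 with 5 seeds per scenario; dose-response
(δ, η ∈ {0, 0.75, 1.5}) and the feature-change and scarcity sweeps at
n = 3,000 with 5 seeds; oracle-equivalence checks use 1,000 random
instances. These sizes give seed-to-seed AUROC sds of roughly 0.01–0.03,
small against the injected effects (0.05–0.2 AUROC), while keeping the full
study at desk scale. The acceptance script uses n = 4,000 for its scenario
battery with both shifts set to 1.5, and 3 seeds per scenario.

## What the generator does not emulate

No real physiology: channels are level-plus-noise around a latent severity,
with no pharmacokinetics, organ coupling, treatment effects, or informative
missingness. Marginal distributions beyond the anchored category mixes are
not matched to any real database. Stays are one per patient; ICU stays last
7–11 days so the staging window is fully observed; mortality and competing
risks are absent (death before readmission is simply "no readmission").
Consequently, passing tests demonstrate that the pipeline measures what it
claims under known shift mechanisms — not that any particular real-world
deployment will show effects of the same size.

## Known limitations

* The latent-risk construction makes vitals/labs independent of the AKI
  trajectory given z; in real data, deterioration and charting intensity
  are coupled.
* Readmission AUROCs at these cohort sizes (≈ 0.58–0.65) sit below what
  large real cohorts support; the signal-to-size ratio of the readmission
  latent model is deliberately modest.
* The brute-force staging oracle and the labeler share the rule
  *interpretation* documented above (baseline definition, interval
  assignment, gap tolerance); the oracle independently verifies the
  implementation, not the interpretation.
* Single-threaded NumPy training is the speed floor; GPU-scale training,
  calibration analysis, and explainability are out of scope.
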