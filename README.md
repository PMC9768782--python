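# icushift

**Dataset-shift evaluation for ICU prediction models on synthetic EHR
cohorts.**

Clinical prediction models degrade when the context they are deployed in
differs from the context they were trained in: clinical practice drifts over
time, hospitals add instruments that produce new features, data for a
condition may be scarce, and patient populations differ between sites.
`icushift` is a reusable pipeline for *quantifying* these losses on
critical-care prediction tasks. It is aimed at researchers in clinical ML
and biostatistics who want a controlled, fully synthetic testbed in which
the size and direction of each context shift is a knob rather than an
accident of the data.

The pipeline has five stages, each usable on its own:

1. **Synthetic cohort generation** — relational ICU tables (patients, stays,
   long-format timestamped observations) with a latent severity vector
   driving both the observed vitals/labs and the ground-truth outcome risks.
   Temporal drift of magnitude δ rotates the post-epoch feature→risk
   coefficients; a population effect of magnitude η does the same for
   non-White patients; one latent component appears only in the urine-output
   channel. Category mixes default to a large single-center critical-care
   database: AKI stage mix 39.9/17.9/32.0/10.2 %, EMR-epoch mix
   50.0/38.6/11.4 %, 71.6 % White, 6.5 % 72-hour ICU readmission rate.
2. **KDIGO AKI staging** — stages 0–3 from creatinine (ratio vs. baseline,
   Δ ≥ 0.3 mg/dL within 48 h, absolute ≥ 4.0 mg/dL) and weight-normalized
   urine output (< 0.5 mL/kg/h for ≥ 6 h / ≥ 12 h; < 0.3 for ≥ 24 h; anuria
   ≥ 12 h), over the first 7 days of the stay. The generator constructs
   trajectories with explicit margins so the labeler recovers the intended
   stage exactly.
3. **Cohort features** — exclusions (age < 18, chronic kidney disease,
   admission AKI, missing staging inputs), an 83-column feature matrix over
   the first 24 h (demographics, comorbidities, vitals/labs summaries,
   a droppable urine group, minimum MDRD-4 eGFR, creatinine summaries), and
   binary labels for seven readmission windows (24 h, 48 h, 72 h, 24–72 h,
   7 d, 30 d, bounce-back).
4. **Models** — multilayer perceptrons (NumPy; ReLU, Adam, class-weighted
   cross-entropy, early stopping) with seeded determinism, stratified-CV
   hyperparameter search, and transfer learning by layer freezing: the input
   layer is widened for new features (old weights copied, new weights zero),
   selected hidden layers stay bitwise frozen, the rest fine-tune.
5. **Scenario engine** — baseline (stratified 80/20), temporal drift
   (train pre-epoch, test post-epoch, crossover stays excluded), change of
   features (three arms over a training-fraction grid: without urine, with
   urine from scratch, with urine via transfer), data scarcity (learning
   curves over random sub-samples), and change of population (train on one
   ethnicity group, test on the others), plus split-confounding tables.

The performance metric throughout is AUROC computed as the Mann–Whitney
concordance, AUROC = (#{s⁺ > s⁻} + ½·#ties) / (n⁺·n⁻), i.e. the probability
that a random positive outscores a random negative with ties half-credited.

## Worked example

```python
import icushift as ic

config = ic.CohortConfig(n_stays=2000, seed=42, drift_magnitude=1.5)
cohort = ic.generate_cohort(config)

labels, eligible, exclusions, y = ic.prepare_task(cohort, "aki_binary")
print(f"eligible stays: {len(eligible)}  (excluded: {len(exclusions)})")
print(f"AKI prevalence: {y.loc[eligible].mean():.3f}")

baseline = ic.run_scenario(ic.ScenarioSpec(kind="baseline", seeds=(0, 1, 2)), cohort)
drift = ic.run_scenario(ic.ScenarioSpec(kind="drift", seeds=(0, 1, 2)), cohort)
print(f"baseline AUROC: {baseline['auroc'].mean():.3f} +/- {baseline['auroc'].std():.3f}")
print(f"drift AUROC:    {drift['auroc'].mean():.3f} +/- {drift['auroc'].std():.3f}")
```

prints

```
eligible stays: 1957  (excluded: 43)
AKI prevalence: 0.593
baseline AUROC: 0.794 +/- 0.009
drift AUROC:    0.729 +/- 0.030
```

With δ = 1.5 the post-epoch feature→risk relationship is rotated away from
the pre-epoch one, so a model trained on pre-epoch stays and transported
across the cut-off loses about 0.07 AUROC relative to the same model trained
and tested on a random split of the full cohort. Setting
`drift_magnitude=0` makes the two numbers statistically indistinguishable.

The same pipeline is available from a shell:

```bash
icushift generate --n-stays 2000 --seed 42 --out cohort/
icushift label --cohort cohort/
icushift features --cohort cohort/ --out feat/
icushift run-scenario --cohort cohort/ --kind drift --seeds 0,1,2 --out results.csv
icushift report --results results.csv
```

Every command writes a JSON manifest (configuration snapshot, seeds, input
fingerprints, row counts) sufficient to re-run it bit-identically.

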