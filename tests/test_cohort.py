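"""Generator contracts: determinism, mixture convergence, risk-model shifts,
and stage-consistent trajectories."""

import numpy as np
import pandas as pd
import pytest

import icushift as ic
from icushift.cohort import BETA, augment_latents


class TestConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ic.ConfigurationError, match="sum to 1"):
            ic.CohortConfig(n_stays=10, stage_mix=(0.5, 0.2, 0.2, 0.2)).validate()

    def test_negative_drift_rejected(self):
        with pytest.raises(ic.ConfigurationError, match="drift"):
            ic.CohortConfig(n_stays=10, drift_magnitude=-1.0).validate()

    def test_tiny_stratum_warns_not_errors(self):
        with pytest.warns(UserWarning, match="stratum"):
            ic.generate_cohort(ic.CohortConfig(n_stays=6, seed=0))

    def test_hospital_prevalence_preset(self):
        mix = ic.hospital_prevalence_stage_mix()
        assert sum(mix) == pytest.approx(1.0)
        assert mix[0] == pytest.approx(0.94)


class TestDeterminism:
    def test_fixed_seed_byte_identical(self):
        cfg = ic.CohortConfig(n_stays=100, seed=7)
        a = ic.generate_cohort(cfg)
        b = ic.generate_cohort(cfg)
        for ta, tb in ((a.patients, b.patients), (a.stays, b.stays),
                       (a.observations, b.observations), (a.truth, b.truth)):
            assert ta.to_csv(index=False) == tb.to_csv(index=False)

    def test_seed_changes_cohort(self):
        a = ic.generate_cohort(ic.CohortConfig(n_stays=100, seed=7))
        b = ic.generate_cohort(ic.CohortConfig(n_stays=100, seed=8))
        assert not a.truth["true_aki_stage"].equals(b.truth["true_aki_stage"])


@pytest.fixture(scope="module")
def cohort4k():
    return ic.generate_cohort(ic.CohortConfig(n_stays=4000, seed=21))


class TestMixConvergence:
    """Empirical category mixes approach the configured mixes (tight 2 %-point
    convergence at n=20,000 is exercised by the acceptance suite)."""

    def test_stage_mix(self, cohort4k):
        frac = cohort4k.truth["true_aki_stage"].value_counts(normalize=True)
        for stage, target in enumerate(ic.CohortConfig().stage_mix):
            assert frac.get(stage, 0.0) == pytest.approx(target, abs=0.03)

    def test_epoch_mix(self, cohort4k):
        frac = cohort4k.stays["emr_epoch"].value_counts(normalize=True)
        for level, target in zip(("pre", "post", "crossover"),
                                 ic.CohortConfig().epoch_mix):
            assert frac.get(level, 0.0) == pytest.approx(target, abs=0.03)

    def test_white_fraction(self, cohort4k):
        white = (cohort4k.patients["ethnicity"] == "White").mean()
        assert white == pytest.approx(0.716, abs=0.03)

    def test_72h_readmission_rate(self, cohort4k):
        gap = cohort4k.truth["true_readmission_gap_h"]
        assert (gap <= 72).mean() == pytest.approx(0.065, abs=0.015)


class TestLatentRisk:
    def test_null_shift_identity_across_epochs(self):
        cfg = ic.CohortConfig(drift_magnitude=0.0, subgroup_effect=0.0)
        x = np.random.default_rng(0).normal(size=BETA.size)
        assert ic.latent_risk(x, "pre", "White", cfg) == ic.latent_risk(
            x, "post", "Black", cfg)

    def test_zero_vector_gives_half(self):
        assert ic.latent_risk(np.zeros(BETA.size), "pre", "White",
                              ic.CohortConfig()) == pytest.approx(0.5)

    def test_drift_raises_post_epoch_risk_when_gamma_dot_x_positive(self):
        from icushift.cohort import GAMMA
        cfg = ic.CohortConfig(drift_magnitude=1.0)
        x = GAMMA / np.linalg.norm(GAMMA)  # gamma.x > 0 by construction
        pre = ic.latent_risk(x, "pre", "White", cfg)
        post = ic.latent_risk(x, "post", "White", cfg)
        assert post > pre

    def test_non_finite_features_rejected(self):
        with pytest.raises(ic.InputError):
            ic.latent_risk(np.full(BETA.size, np.nan), "pre", "White",
                           ic.CohortConfig())

    def test_monotone_shift_in_delta(self):
        """Mean absolute pre/post risk gap on a fixed grid grows with delta."""
        rng = np.random.default_rng(11)
        grid = augment_latents(rng.normal(size=(200, 8)))
        gaps = []
        for delta in (0.0, 0.5, 1.0, 1.5):
            cfg = ic.CohortConfig(drift_magnitude=delta)
            diff = [abs(ic.latent_risk(x, "post", "White", cfg)
                        - ic.latent_risk(x, "pre", "White", cfg)) for x in grid]
            gaps.append(np.mean(diff))
        assert all(b >= a for a, b in zip(gaps, gaps[1:]))
        assert gaps[0] == 0.0


class TestTrajectories:
    def test_stage0_never_crosses_any_threshold(self):
        for seed in range(10):
            chans = ic.trajectory_from_stage(0, 80.0, True, seed)
            t, v = chans["creatinine"]
            res = ic.kdigo_stage(
                ic.ChannelSeries("s", "creatinine", t, v),
                ic.ChannelSeries("s", "urine_output", *chans["urine_output"], 80.0),
                80.0)
            assert res.stage == 0
            ut, uv = chans["urine_output"]
            assert (uv / 80.0 >= 0.5).all()

    def test_stage3_without_urine_reaches_3x_baseline(self):
        chans = ic.trajectory_from_stage(3, 70.0, False, seed=5)
        t, v = chans["creatinine"]
        assert "urine_output" not in chans
        baseline = v[t <= 24].min()
        assert v.max() >= 3.0 * baseline
        res = ic.kdigo_stage(ic.ChannelSeries("s", "creatinine", t, v), None, 70.0)
        assert res.stage == 3

    def test_all_channels_emitted(self):
        chans = ic.trajectory_from_stage(1, 70.0, True, seed=1)
        for name in ("creatinine", "urine_output", "heart_rate", "bun",
                     "hemoglobin", "wbc", "respiration_rate"):
            assert name in chans
            t, v = chans[name]
            assert (np.diff(t) > 0).all() and (v >= 0).all()

    @pytest.mark.parametrize("urine_available", [True, False])
    def test_labeler_recovers_intended_stage(self, urine_available):
        rng = np.random.default_rng(42)
        for _ in range(150):
            stage = int(rng.integers(0, 4))
            weight = float(rng.uniform(60, 110))
            chans = ic.trajectory_from_stage(stage, weight, urine_available,
                                             int(rng.integers(0, 2**31)))
            creat = ic.ChannelSeries("s", "creatinine", *chans["creatinine"])
            urine = None
            if urine_available:
                urine = ic.ChannelSeries("s", "urine_output",
                                         *chans["urine_output"], weight)
            assert ic.kdigo_stage(creat, urine, weight).stage == stage


class TestCohortStructure:
    def test_referential_and_time_invariants(self, small_cohort):
        c = small_cohort
        assert set(c.observations["stay_id"].unique()) <= set(c.stays["stay_id"])
        assert set(c.truth["stay_id"]) == set(c.stays["stay_id"])
        assert (c.stays["icu_admit_time"] < c.stays["icu_discharge_time"]).all()
        readmit = c.stays["readmission_time"].dropna()
        assert (readmit > c.stays.loc[readmit.index, "icu_discharge_time"]).all()
        assert (c.patients["age_years"] >= 18).all()

    def test_round_trip_fidelity_on_generated_cohort(self, small_cohort):
        labels = ic.label_cohort(small_cohort.observations, small_cohort.stays,
                                 small_cohort.patients)
        merged = labels.merge(small_cohort.truth, on="stay_id")
        assert (merged["stage"] == merged["true_aki_stage"]).all()

    def test_urine_unavailable_cohort_has_no_urine_channel(self):
        c = ic.generate_cohort(ic.CohortConfig(n_stays=60, seed=2,
                                               urine_available=False))
        assert "urine_output" not in set(c.observations["channel"].unique())
        labels = ic.label_cohort(c.observations, c.stays, c.patients)
        merged = labels.merge(c.truth, on="stay_id")
        assert (merged["stage"] == merged["true_aki_stage"]).all()
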