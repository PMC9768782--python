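import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import icushift as ic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared across tests (n=400, default mixes)."""
    return ic.generate_cohort(ic.CohortConfig(n_stays=400, seed=3))


@pytest.fixture(scope="session")
def small_task(small_cohort):
    """(labels_df, eligible, exclusions, y) for the binary AKI task."""
    return ic.prepare_task(small_cohort, "aki_binary")


def toy_cohort(patient_rows, stay_rows, obs_rows):
    """Assemble a hand-built Cohort from row dicts, filling schema defaults."""
    pat_defaults = dict(ethnicity="White", age_years=50.0, sex="M",
                        weight_kg=80.0, chronic_kidney_disease=0)
    for c in ("congestive_heart_failure", "hypertension", "diabetes", "copd",
              "atrial_fibrillation", "coronary_artery_disease", "stroke",
              "cancer", "liver_disease", "obesity"):
        pat_defaults[c] = 0
    stay_defaults = dict(icu_admit_time=0.0, icu_discharge_time=200.0,
                         hospital_discharge_time=260.0, emr_epoch="pre",
                         readmission_time=np.nan)
    patients = pd.DataFrame([{**pat_defaults, **r} for r in patient_rows],
                            columns=["patient_id", *pat_defaults])
    stays = pd.DataFrame([{**stay_defaults, **r} for r in stay_rows],
                         columns=["stay_id", "patient_id", *stay_defaults])
    obs = pd.DataFrame(obs_rows, columns=["stay_id", "time_h", "channel", "value"])
    obs["units"] = obs["channel"].map(ic.metrics.CHANNEL_UNITS)
    truth = pd.DataFrame({"stay_id": stays["stay_id"], "true_aki_stage": 0,
                          "true_readmission_gap_h": np.nan})
    return ic.Cohort(patients, stays, obs, truth, {})


def flat_creatinine_obs(stay_id, value=0.9, every_h=12.0):
    times = np.arange(2.0, 160.0, every_h)
    return [(stay_id, t, "creatinine", value) for t in times]
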