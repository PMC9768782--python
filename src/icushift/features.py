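"""Cohort exclusions, the 83-column AKI feature matrix, and readmission labels.

The feature matrix summarizes the first 24 h of each stay (the prediction
window: features must precede most AKI onsets, which the labeler looks for
over days 0-7).  The 83 columns break down as 4 demographics, 10 comorbidity
flags, 13 vitals/labs channels x 4 summary statistics, 3 urine features
(droppable as a group for the change-of-features scenario), minimum eGFR,
and 13 creatinine-derived features.  eGFR uses the 4-variable MDRD equation,
the creatinine-based estimate standard in ICU laboratory reporting of the
source era.

Normalization (per-feature mean/sd) and median imputation are fitted on
training rows only; raw summaries never depend on the train/test flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kdigo
from .cohort import Cohort, COMORBIDITIES, VITAL_CHANNELS, LAB_CHANNELS
from .errors import DataError, InputError, SchemaError

FEATURE_WINDOW_H = 24.0
OLIGURIA_RATE = 0.5  # mL/kg/h, the stage-1 urine threshold

SUMMARY_STATS = ("mean", "min", "max", "last")
URINE_FEATURES = ("urine_rate_mean_24h", "urine_rate_min_24h",
                  "urine_hours_below_0p5")
READMISSION_WINDOWS = ("24h", "48h", "72h", "24_72h", "7d", "30d", "bounce_back")
_WINDOW_HOURS = {"24h": 24.0, "48h": 48.0, "72h": 72.0, "7d": 168.0, "30d": 720.0}


def feature_names(include_urine: bool = True) -> list[str]:
    """Fixed, documented column order of the feature matrix."""
    names = ["age_years", "sex_male", "weight_kg", "ethnicity_white"]
    names += [f"comorb_{c}" for c in COMORBIDITIES]
    for channel in VITAL_CHANNELS + LAB_CHANNELS:
        names += [f"{channel}_{s}" for s in SUMMARY_STATS]
    if include_urine:
        names += list(URINE_FEATURES)
    names += ["egfr_min"]
    names += ["crea_mean", "crea_min", "crea_max", "crea_first", "crea_last",
              "crea_sd", "crea_count", "crea_delta_24h", "crea_ratio_max_min",
              "crea_slope_24h", "egfr_first", "egfr_last", "bun_crea_ratio"]
    return names


def egfr(creatinine: float, age_years: float, sex: str, ethnicity: str) -> float:
    """MDRD-4 estimated glomerular filtration rate (mL/min/1.73 m^2).

    175 * SCr^-1.154 * age^-0.203 * 0.742 [female] * 1.212 [Black].
    """
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise InputError("creatinine must be positive")
    value = 175.0 * creatinine ** -1.154 * float(age_years) ** -0.203
    if sex == "F":
        value = value * 0.742
    if ethnicity == "Black":
        value = value * 1.212
    return value if np.ndim(value) else float(value)


def extract_cohort(cohort: Cohort, labels: pd.DataFrame
                   ) -> tuple[list[str], pd.DataFrame]:
    """Apply the cohort exclusions; returns (eligible stay_ids, exclusions).

    Excluded: age < 18, chronic kidney disease, uncomputable KDIGO inputs
    (no creatinine baseline), and AKI already present in the first 24 h of
    the stay (admission AKI).  Each excluded stay carries one reason (first
    matching, in that order).
    """
    for col in ("stay_id", "patient_id"):
        if col not in cohort.stays.columns:
            raise SchemaError(f"stays: missing column {col}")
    pat = cohort.patients.set_index("patient_id")
    lab = labels.set_index("stay_id")
    eligible: list[str] = []
    excluded: list[tuple[str, str]] = []
    for stay_id, patient_id in zip(cohort.stays["stay_id"], cohort.stays["patient_id"]):
        p = pat.loc[patient_id]
        row = lab.loc[stay_id]
        if p["age_years"] < 18:
            excluded.append((stay_id, "age_under_18"))
        elif int(p.get("chronic_kidney_disease", 0)) == 1:
            excluded.append((stay_id, "chronic_kidney_disease"))
        elif row["stage"] == -1 or row["error"] == "missing_baseline":
            excluded.append((stay_id, "missing_baseline"))
        elif row["stage"] >= 1 and row["onset_time_h"] <= kdigo.BASELINE_WINDOW_H:
            excluded.append((stay_id, "admission_aki"))
        else:
            eligible.append(stay_id)
    exclusions = pd.DataFrame(excluded, columns=["stay_id", "reason"])
    return eligible, exclusions


@dataclass
class FeatureMatrix:
    """Per-stay features with train-only normalization and imputation.

    ``values`` holds the raw summaries (NaN where a summary is missing);
    ``design_matrix()`` returns the imputed, standardized matrix.  Refitting
    with a different train flagging changes only the fitted parameters.
    """

    stay_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    urine_group: tuple[str, ...]
    train_mask: np.ndarray
    medians: np.ndarray = field(init=False)
    norm_mean: np.ndarray = field(init=False)
    norm_sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.stay_ids), len(self.feature_names)):
            raise InputError("values shape does not match stay_ids x feature_names")
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        if not self.train_mask.any():
            raise InputError("at least one training row is required to fit parameters")
        self.refit(self.train_mask)

    def refit(self, train_mask: np.ndarray) -> None:
        """Fit imputation medians and normalization on the flagged rows only."""
        self.train_mask = np.asarray(train_mask, dtype=bool)
        train = self.values[self.train_mask]
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.medians = np.nanmedian(train, axis=0)
        self.medians = np.where(np.isfinite(self.medians), self.medians, 0.0)
        imputed = np.where(np.isnan(train), self.medians, train)
        self.norm_mean = imputed.mean(axis=0)
        sd = imputed.std(axis=0)
        self.norm_sd = np.where(sd > 1e-12, sd, 1.0)

    def design_matrix(self) -> np.ndarray:
        imputed = np.where(np.isnan(self.values), self.medians, self.values)
        return (imputed - self.norm_mean) / self.norm_sd

    @property
    def index(self) -> pd.Index:
        return pd.Index(self.stay_ids, name="stay_id")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index, columns=self.feature_names)


def _summaries(obs: pd.DataFrame, stay_ids: list[str], channels) -> pd.DataFrame:
    """(mean, min, max, last) of each channel over the first 24 h, per stay."""
    w = obs[obs["channel"].isin(channels) & (obs["time_h"] <= FEATURE_WINDOW_H)]
    w = w.sort_values("time_h", kind="stable")
    g = w.groupby(["stay_id", "channel"], observed=True)["value"]
    agg = g.agg(["mean", "min", "max", "last"])
    wide = agg.unstack("channel")
    cols = {}
    for channel in channels:
        for stat in SUMMARY_STATS:
            key = (stat, channel)
            cols[f"{channel}_{stat}"] = wide[key] if key in wide.columns else np.nan
    out = pd.DataFrame(cols)
    return out.reindex(stay_ids)


def build_features(cohort: Cohort, eligible_ids: list[str],
                   include_urine: bool = True,
                   train_ids: set[str] | list[str] | None = None,
                   ) -> FeatureMatrix:
    """Assemble the feature matrix for the eligible stays.

    ``train_ids`` flags the rows used to fit imputation and normalization
    (default: all rows — refit later via FeatureMatrix.refit for a real
    split).  Unknown observation channels are ignored.
    """
    names = feature_names(include_urine)
    stays = cohort.stays.set_index("stay_id").loc[eligible_ids]
    patients = cohort.patients.set_index("patient_id").loc[stays["patient_id"]]
    patients.index = stays.index

    obs = cohort.observations
    obs = obs[obs["stay_id"].isin(set(eligible_ids))]

    frame = pd.DataFrame(index=pd.Index(eligible_ids, name="stay_id"))
    frame["age_years"] = patients["age_years"]
    frame["sex_male"] = (patients["sex"] == "M").astype(float)
    frame["weight_kg"] = patients["weight_kg"]
    frame["ethnicity_white"] = (patients["ethnicity"] == "White").astype(float)
    for c in COMORBIDITIES:
        frame[f"comorb_{c}"] = patients[c].astype(float)

    vl = _summaries(obs, eligible_ids, list(VITAL_CHANNELS + LAB_CHANNELS))
    frame = frame.join(vl)

    if include_urine:
        frame = frame.join(_urine_features(obs, eligible_ids, patients["weight_kg"]))

    frame = frame.join(_creatinine_features(obs, eligible_ids, patients))

    missing = [c for c in names if c not in frame.columns]
    if missing:
        raise SchemaError(f"internal: features not assembled: {missing}")
    frame = frame[names]
    ids = list(frame.index)
    if train_ids is None:
        train_mask = np.ones(len(ids), dtype=bool)
    else:
        train_ids = set(train_ids)
        train_mask = np.array([s in train_ids for s in ids])
    return FeatureMatrix(ids, names, frame.to_numpy(dtype=float),
                         URINE_FEATURES if include_urine else (), train_mask)


def _urine_features(obs: pd.DataFrame, stay_ids: list[str],
                    weights: pd.Series) -> pd.DataFrame:
    u = obs[(obs["channel"] == "urine_output") & (obs["time_h"] <= FEATURE_WINDOW_H)]
    u = u.sort_values("time_h", kind="stable")
    rows = {}
    for stay_id, g in u.groupby("stay_id", observed=True):
        w = float(weights.get(stay_id, np.nan))
        t = g["time_h"].to_numpy(float)
        rate = g["value"].to_numpy(float) / w
        starts = np.concatenate([[0.0], t[:-1]])
        lengths = t - starts
        below = float(lengths[rate < OLIGURIA_RATE].sum())
        rows[stay_id] = (float(rate.mean()), float(rate.min()), below)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=URINE_FEATURES)
    return out.reindex(stay_ids)


def _creatinine_features(obs: pd.DataFrame, stay_ids: list[str],
                         patients: pd.DataFrame) -> pd.DataFrame:
    c = obs[(obs["channel"] == "creatinine") & (obs["time_h"] <= FEATURE_WINDOW_H)]
    c = c.sort_values("time_h", kind="stable")
    g = c.groupby("stay_id", observed=True)
    agg = g["value"].agg(["mean", "min", "max", "first", "last", "std", "count"])
    agg.columns = ["crea_mean", "crea_min", "crea_max", "crea_first",
                   "crea_last", "crea_sd", "crea_count"]
    agg = agg.reindex(stay_ids)
    agg["crea_delta_24h"] = agg["crea_max"] - agg["crea_min"]
    agg["crea_ratio_max_min"] = agg["crea_max"] / agg["crea_min"]
    tspan = g["time_h"].agg(lambda t: t.iloc[-1] - t.iloc[0]).reindex(stay_ids)
    with np.errstate(all="ignore"):
        slope = (agg["crea_last"] - agg["crea_first"]) / tspan
    agg["crea_slope_24h"] = slope.where(tspan > 0)

    age = patients["age_years"].reindex(stay_ids)
    female = (patients["sex"] == "F").reindex(stay_ids)
    black = (patients["ethnicity"] == "Black").reindex(stay_ids)
    factor = (175.0 * age.to_numpy(float) ** -0.203
              * np.where(female, 0.742, 1.0) * np.where(black, 1.212, 1.0))

    def _egfr(col):
        v = agg[col].to_numpy(float)
        with np.errstate(all="ignore"):
            return np.where(v > 0, factor * v ** -1.154, np.nan)

    agg["egfr_min"] = _egfr("crea_max")  # min eGFR corresponds to max creatinine
    agg["egfr_first"] = _egfr("crea_first")
    agg["egfr_last"] = _egfr("crea_last")

    bun = obs[(obs["channel"] == "bun") & (obs["time_h"] <= FEATURE_WINDOW_H)]
    bun_mean = bun.groupby("stay_id", observed=True)["value"].mean().reindex(stay_ids)
    with np.errstate(all="ignore"):
        agg["bun_crea_ratio"] = bun_mean / agg["crea_mean"]
    return agg


def readmission_labels(stays: pd.DataFrame) -> pd.DataFrame:
    """Binary labels for the seven readmission windows, one row per stay.

    gap = readmission_time - icu_discharge_time.  Cumulative windows label 1
    iff gap <= window; the 24-72 h window labels 1 iff 24 < gap <= 72;
    bounce-back labels 1 iff the readmission occurs before hospital
    discharge.  No readmission means all labels 0.
    """
    gap = stays["readmission_time"] - stays["icu_discharge_time"]
    if (gap.dropna() <= 0).any():
        bad = stays.loc[gap.dropna().index[gap.dropna() <= 0], "stay_id"].tolist()[:5]
        raise DataError(f"readmission at/before ICU discharge for stays {bad}")
    out = pd.DataFrame({"stay_id": stays["stay_id"], "gap_h": gap})
    readmitted = gap.notna()
    for w in ("24h", "48h", "72h", "7d", "30d"):
        out[w] = (readmitted & (gap <= _WINDOW_HOURS[w])).astype(int)
    out["24_72h"] = (readmitted & (gap > 24.0) & (gap <= 72.0)).astype(int)
    out["bounce_back"] = (
        readmitted & (stays["readmission_time"] < stays["hospital_discharge_time"])
    ).astype(int)
    return out[["stay_id", "gap_h", *READMISSION_WINDOWS]]
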