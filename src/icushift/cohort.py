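"""Synthetic ICU cohort generator with controllable context shifts.

Emulates the relational structure of a critical-care EHR extract — patients,
ICU stays, and long-format timestamped observations — with the statistical
structure the deployment-scenario experiments need:

* a latent per-stay severity vector z drives both the observed vitals/labs
  and the ground-truth AKI and readmission risks, so summary features are
  genuinely predictive;
* temporal drift (``drift_magnitude``, delta) rotates the feature-to-risk
  coefficients in the post-epoch records (a pure mean shift would be absorbed
  by normalization and make the drift scenario trivially null);
* a population effect (``subgroup_effect``, eta) rotates the coefficients for
  non-White patients the same way;
* one latent component appears *only* in the urine-output channel, planting a
  urine-specific signal for the change-of-features scenario;
* two interaction terms enter the risk but not the observed channels
  directly, planting a nonlinearity that separates deep from shallow models.

Creatinine and urine-output trajectories are constructed *from* each stay's
intended AKI stage with explicit margins around every KDIGO threshold, so the
staging labeler recovers the intended stage exactly (round-trip fidelity).
Default category mixes are anchored to a large single-center critical-care
database: AKI stage mix (39.9 / 17.9 / 32.0 / 10.2 %), EMR-epoch mix
(50.0 / 38.6 / 11.4 %), White fraction 71.6 %, and a 6.5 % 72-hour ICU
readmission rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import lognorm

from .errors import ConfigurationError, InputError
from .metrics import CHANNEL_UNITS

GENERATOR_VERSION = "1.0"

ETHNICITIES = ("White", "Black", "Latinx", "Other")
EPOCHS = ("pre", "post", "crossover")
STAGES = (0, 1, 2, 3)

LATENT_DIM = 8  # z7 is the urine-only latent
_N_AUGMENT = 2  # z0*z1 and z6^2-1 interaction terms appended to z

# Risk coefficients on the augmented vector [z0..z7, z0*z1, z6^2 - 1].
# BETA is the base regime; GAMMA rotates it under drift (delta) and KAPPA
# under a population change (eta).  GAMMA and KAPPA are roughly orthogonal to
# BETA so increasing delta/eta monotonically decorrelates the regimes.
BETA = np.array([0.9, 0.8, -0.7, 0.6, 0.5, -0.4, 0.0, 1.3, 0.8, 0.6])
GAMMA = np.array([-0.8, 0.9, 0.7, -0.6, 0.7, 0.5, 0.0, 0.0, -0.7, 0.5])
KAPPA = np.array([0.6, -0.8, 0.7, 0.7, -0.6, 0.5, 0.0, 0.0, 0.6, -0.5])

# Readmission risk operates on z directly (no planted interactions).
THETA = np.array([0.5, -0.4, 0.4, 0.3, -0.3, 0.3, 0.2, 0.4])
THETA_GAMMA = np.array([-0.4, 0.3, 0.3, -0.3, 0.2, 0.2, 0.3, -0.2])
THETA_KAPPA = np.array([0.3, 0.3, -0.3, 0.2, 0.3, -0.2, 0.2, -0.3])

# channel -> (population mean, population sd, loadings on z0..z6)
CHANNELS: dict[str, tuple[float, float, dict[int, float]]] = {
    "heart_rate": (85.0, 12.0, {0: 0.6, 4: 0.3}),
    "systolic_bp": (120.0, 18.0, {1: -0.6, 5: 0.3}),
    "diastolic_bp": (65.0, 10.0, {1: -0.5, 6: 0.3}),
    "mean_bp": (83.0, 12.0, {1: -0.55, 3: 0.25}),
    "respiration_rate": (18.0, 3.5, {2: 0.6, 0: 0.3}),
    "spo2": (96.5, 1.5, {2: -0.5, 6: 0.3}),
    "temperature": (37.0, 0.5, {3: 0.5, 4: 0.3}),
    "bun": (22.0, 8.0, {3: 0.6, 2: 0.3}),
    "hemoglobin": (10.8, 1.8, {4: -0.6, 1: 0.3}),
    "wbc": (10.0, 3.5, {5: 0.6, 3: 0.3}),
    "sodium": (139.0, 4.0, {6: 0.5, 5: 0.3}),
    "potassium": (4.1, 0.5, {6: 0.5, 2: 0.35}),
    "glucose": (135.0, 35.0, {5: 0.55, 6: 0.3}),
}
VITAL_CHANNELS = ("heart_rate", "systolic_bp", "diastolic_bp", "mean_bp",
                  "respiration_rate", "spo2", "temperature")
LAB_CHANNELS = ("bun", "hemoglobin", "wbc", "sodium", "potassium", "glucose")

VITALS_SPAN_H = 48.0   # vitals charted hourly over the first 48 h
SERIES_SPAN_H = 168.0  # creatinine/urine/labs span the 7-day staging window

COMORBIDITIES = ("congestive_heart_failure", "hypertension", "diabetes",
                 "copd", "atrial_fibrillation", "coronary_artery_disease",
                 "stroke", "cancer", "liver_disease", "obesity")
# baseline prevalence; the first three are tilted by a latent component
COMORBIDITY_PREVALENCE = (0.18, 0.40, 0.26, 0.12, 0.15, 0.14,
                          0.07, 0.10, 0.05, 0.20)
CKD_PREVALENCE = 0.02  # chronic kidney disease: exclusion flag only

# Readmission gap mixture: early bounce-back vs late return (hours)
GAP_EARLY_WEIGHT = 0.35
GAP_EARLY_MEDIAN_H = 36.0
GAP_EARLY_SIGMA = 0.8
GAP_LATE_MEDIAN_H = 400.0
GAP_LATE_SIGMA = 0.9


def hospital_prevalence_stage_mix(aki_rate: float = 0.06
                                  ) -> tuple[float, float, float, float]:
    """Alternative stage mix preset at hospital-wide AKI prevalence (5-7 % of
    all hospitalizations), keeping the ICU cohort's conditional stage split."""
    cond = np.array([7558.0, 13535.0, 4321.0])
    cond = cond / cond.sum()
    return (1.0 - aki_rate, *(float(aki_rate * c) for c in cond))


def _default_cadence() -> dict[str, float]:
    return {"creatinine": 12.0, "urine_output": 1.0, "vitals": 1.0, "labs": 24.0}


@dataclass(frozen=True)
class CohortConfig:
    """Knobs standing in for the data contexts of the shift experiments."""

    n_stays: int = 1000
    seed: int = 0
    ethnicity_mix: tuple[float, float, float, float] = (0.716, 0.075, 0.034, 0.175)
    epoch_mix: tuple[float, float, float] = (0.500, 0.386, 0.114)
    stage_mix: tuple[float, float, float, float] = (
        16837 / 42251, 7558 / 42251, 13535 / 42251, 4321 / 42251)
    readmission_rate_72h: float = 0.065
    drift_magnitude: float = 0.0    # delta
    subgroup_effect: float = 0.0    # eta
    urine_available: bool = True
    noise_sd: float = 0.35          # observation noise, in channel-sd units
    obs_cadence: dict = field(default_factory=_default_cadence)

    def validate(self) -> None:
        if self.n_stays < 1:
            raise ConfigurationError("n_stays must be >= 1")
        for name, mix, k in (("ethnicity_mix", self.ethnicity_mix, 4),
                             ("epoch_mix", self.epoch_mix, 3),
                             ("stage_mix", self.stage_mix, 4)):
            mix = np.asarray(mix, dtype=float)
            if mix.shape != (k,) or (mix < 0).any():
                raise ConfigurationError(f"{name} must be {k} non-negative proportions")
            if abs(mix.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {mix.sum():.12f})")
        if not 0.0 <= self.readmission_rate_72h <= 1.0:
            raise ConfigurationError("readmission_rate_72h must be in [0, 1]")
        for name, v in (("drift_magnitude", self.drift_magnitude),
                        ("subgroup_effect", self.subgroup_effect)):
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0")
        if not (np.isfinite(self.noise_sd) and self.noise_sd > 0):
            raise ConfigurationError("noise_sd must be finite and > 0")
        for mix, levels, name in ((self.stage_mix, STAGES, "stage"),
                                  (self.epoch_mix, EPOCHS, "epoch"),
                                  (self.ethnicity_mix, ETHNICITIES, "ethnicity")):
            for p, level in zip(mix, levels):
                if 0 < p * self.n_stays < 1:
                    warnings.warn(
                        f"n_stays={self.n_stays} likely leaves {name} stratum "
                        f"{level!r} empty", stacklevel=2)


@dataclass
class Cohort:
    """Generated cohort: four relational tables plus the generation manifest."""

    patients: pd.DataFrame
    stays: pd.DataFrame
    observations: pd.DataFrame
    truth: pd.DataFrame
    manifest: dict


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def augment_latents(z: np.ndarray) -> np.ndarray:
    """Append the planted interaction terms z0*z1 and z6^2 - 1."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    extra = np.column_stack([z[:, 0] * z[:, 1], z[:, 6] ** 2 - 1.0])
    return np.hstack([z, extra])


def latent_risk(features, epoch: str, ethnicity: str, config: CohortConfig,
                intercept: float = 0.0) -> float:
    """Ground-truth AKI probability for one augmented feature vector.

    logistic(beta.x + delta*[epoch==post]*(gamma.x)
             + eta*[ethnicity!=White]*(kappa.x) + intercept)
    """
    x = np.asarray(features, dtype=float)
    if x.shape != BETA.shape:
        raise InputError(f"features must have length {BETA.size}")
    if not np.all(np.isfinite(x)):
        raise InputError("features must be finite")
    config.validate()
    score = float(BETA @ x)
    if epoch == "post":
        score += config.drift_magnitude * float(GAMMA @ x)
    if ethnicity != "White":
        score += config.subgroup_effect * float(KAPPA @ x)
    return float(_sigmoid(score + intercept))


def _calibrate_intercept(scores: np.ndarray, target_rate: float) -> float:
    """Intercept b0 with mean(sigmoid(scores + b0)) == target_rate."""
    if target_rate <= 0:
        return -30.0
    if target_rate >= 1:
        return 30.0
    return float(brentq(lambda b: _sigmoid(scores + b).mean() - target_rate, -30, 30))


def _jittered_times(rng, start: float, cadence: float, span: float) -> np.ndarray:
    base = np.arange(start, span, cadence)
    t = base + rng.uniform(-0.2, 0.2, base.size) * cadence
    return np.clip(t, 0.05, None)


# ---------------------------------------------------------------------------
# Stage-consistent creatinine / urine trajectories

# (low ratio, high ratio) of peak creatinine vs observed baseline, and the
# clip ceiling keeping the series inside its stage band
_CREAT_PEAK = {1: (1.62, 1.85, 1.95), 2: (2.15, 2.85, 2.95), 3: (3.30, 3.90, np.inf)}
# (low rate, high rate) mL/kg/h and (low, high) episode duration in hours
_URINE_EPISODE = {1: (0.35, 0.45, 7.5, 10.0), 2: (0.33, 0.45, 13.5, 20.0),
                  3: (0.12, 0.25, 26.0, 40.0)}


def _flat_creatinine(rng, times: np.ndarray, baseline: float) -> np.ndarray:
    noise = np.clip(rng.normal(0.0, 0.03, times.size), -0.07, 0.07)
    return baseline + noise


def _stage_channels(stage: int, weight_kg: float, urine_available: bool,
                    rng: np.random.Generator, cadence: dict[str, float],
                    base_urine_rate: float | None = None,
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Creatinine (and optionally urine) series realizing one AKI stage.

    Thresholds are approached with explicit margins so KDIGO staging of the
    output recovers `stage` deterministically.  For stages >= 1 the injury is
    written into the urine channel (weight-normalized oliguria episode) with
    probability 1/2 when urine is available, else into creatinine.
    """
    if not weight_kg > 0:
        raise InputError("weight_kg must be positive")
    t_creat = _jittered_times(rng, 2.0, cadence["creatinine"], SERIES_SPAN_H - 8.0)
    b = rng.uniform(0.65, 1.05)
    use_urine_arm = bool(stage >= 1 and urine_available and rng.random() < 0.5)

    if stage == 0 or use_urine_arm:
        creat = _flat_creatinine(rng, t_creat, b)
    else:
        creat = _flat_creatinine(rng, t_creat, b)
        baseline_obs = creat[t_creat <= 24.0].min()
        lo_ratio, hi_ratio, cap = _CREAT_PEAK[stage]
        peak = rng.uniform(lo_ratio, hi_ratio) * baseline_obs
        rise_start = rng.uniform(30.0, 60.0)
        rise_end = rise_start + rng.uniform(18.0, 36.0)
        ramp = t_creat > rise_start
        frac = np.clip((t_creat[ramp] - rise_start) / (rise_end - rise_start), 0, 1)
        v = b + frac * (peak - b) + rng.normal(0.0, 0.02, frac.size)
        # stay inside the intended band: below the next stage's threshold,
        # and (on the plateau) above this stage's own threshold
        v = np.minimum(v, cap * baseline_obs - 1e-3)
        plateau = frac >= 1.0
        v[plateau] = np.clip(v[plateau], (lo_ratio - 0.02) * baseline_obs, None)
        creat = creat.copy()
        creat[ramp] = v

    out = {"creatinine": (t_creat, creat)}
    if urine_available:
        t_ur = _jittered_times(rng, 0.6, cadence["urine_output"], SERIES_SPAN_H - 2.0)
        if base_urine_rate is None:
            base_urine_rate = rng.uniform(0.7, 1.4)
        base_urine_rate = max(base_urine_rate, 0.6)
        rate = base_urine_rate * np.clip(rng.normal(1.0, 0.05, t_ur.size), 0.9, 1.1)
        if use_urine_arm:
            lo_r, hi_r, lo_d, hi_d = _URINE_EPISODE[stage]
            ep_start = rng.uniform(26.0, 80.0)
            ep_dur = rng.uniform(lo_d, hi_d)
            low = (t_ur > ep_start) & (t_ur <= ep_start + ep_dur)
            ep_rate = rng.uniform(lo_r, hi_r)
            rate[low] = ep_rate * np.clip(rng.normal(1.0, 0.02, low.sum()), 0.97, 1.03)
        out["urine_output"] = (t_ur, rate * weight_kg)
    return out


def trajectory_from_stage(stage: int, weight_kg: float, urine_available: bool,
                          seed: int, base_urine_rate: float | None = None,
                          channel_offsets: dict[str, float] | None = None,
                          ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Full observation series for one stay with the intended KDIGO stage.

    Returns channel -> (times_h, values): creatinine (mg/dL), urine output
    (mL/h, iff available), hourly vitals over the first 48 h, and daily labs.
    ``channel_offsets`` shifts a vitals/labs channel's per-stay level (the
    cohort generator uses this to write the latent severity into the series).
    """
    if stage not in STAGES:
        raise InputError(f"stage must be one of {STAGES}")
    rng = np.random.default_rng(seed)
    cadence = _default_cadence()
    out = _stage_channels(stage, weight_kg, urine_available, rng, cadence,
                          base_urine_rate)
    offsets = channel_offsets or {}
    for name in VITAL_CHANNELS + LAB_CHANNELS:
        mean, sd, _ = CHANNELS[name]
        if name in VITAL_CHANNELS:
            t = _jittered_times(rng, 0.5, cadence["vitals"], VITALS_SPAN_H)
        else:
            t = _jittered_times(rng, 6.0, cadence["labs"], SERIES_SPAN_H)
        v = mean + offsets.get(name, 0.0) + rng.normal(0.0, 0.35 * sd, t.size)
        out[name] = (t, np.maximum(v, 0.0))
    return out


# ---------------------------------------------------------------------------
# Cohort assembly


def _gap_distribution_cdf_72h() -> float:
    early = lognorm(GAP_EARLY_SIGMA, scale=GAP_EARLY_MEDIAN_H)
    late = lognorm(GAP_LATE_SIGMA, scale=GAP_LATE_MEDIAN_H)
    return float(GAP_EARLY_WEIGHT * early.cdf(72.0)
                 + (1 - GAP_EARLY_WEIGHT) * late.cdf(72.0))


def _draw_gaps(rng, n: int) -> np.ndarray:
    early = rng.random(n) < GAP_EARLY_WEIGHT
    gaps = np.where(
        early,
        rng.lognormal(np.log(GAP_EARLY_MEDIAN_H), GAP_EARLY_SIGMA, n),
        rng.lognormal(np.log(GAP_LATE_MEDIAN_H), GAP_LATE_SIGMA, n),
    )
    return np.maximum(gaps, 0.5)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Deterministically generate a cohort from its configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stays

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    stay_ids = np.array([f"S{i:06d}" for i in range(n)])
    ethnicity = rng.choice(ETHNICITIES, size=n, p=config.ethnicity_mix)
    epoch = rng.choice(EPOCHS, size=n, p=config.epoch_mix)
    age = np.round(rng.uniform(18.0, 90.0, n), 1)
    sex = rng.choice(["F", "M"], size=n)
    weight = np.round(rng.uniform(60.0, 110.0, n), 1)

    z = rng.standard_normal((n, LATENT_DIM))
    x = augment_latents(z)

    comorb = {}
    tilt = {"congestive_heart_failure": 2, "hypertension": 3, "diabetes": 5}
    for name, prev in zip(COMORBIDITIES, COMORBIDITY_PREVALENCE):
        logit = np.log(prev / (1 - prev)) + 0.6 * z[:, tilt[name]] if name in tilt \
            else np.full(n, np.log(prev / (1 - prev)))
        comorb[name] = (rng.random(n) < _sigmoid(logit)).astype(int)
    ckd = (rng.random(n) < CKD_PREVALENCE).astype(int)

    # ground-truth AKI risk; crossover stays mix the pre and post regimes
    post_like = (epoch == "post") | ((epoch == "crossover") & (rng.random(n) < 0.5))
    nonwhite = ethnicity != "White"
    score = x @ BETA \
        + config.drift_magnitude * post_like * (x @ GAMMA) \
        + config.subgroup_effect * nonwhite * (x @ KAPPA)
    aki_rate = 1.0 - config.stage_mix[0]
    b0 = _calibrate_intercept(score, aki_rate)
    aki = rng.random(n) < _sigmoid(score + b0)
    stage = np.zeros(n, dtype=int)
    if aki.any():
        cond = np.asarray(config.stage_mix[1:], dtype=float)
        stage[aki] = rng.choice([1, 2, 3], size=int(aki.sum()), p=cond / cond.sum())

    # readmission: flag from latent risk, gap from the bounce-back mixture
    r_score = z @ THETA \
        + config.drift_magnitude * post_like * (z @ THETA_GAMMA) \
        + config.subgroup_effect * nonwhite * (z @ THETA_KAPPA)
    p_any = min(config.readmission_rate_72h / _gap_distribution_cdf_72h(), 1.0)
    if config.readmission_rate_72h > 0:
        c0 = _calibrate_intercept(r_score, p_any)
        readmit = rng.random(n) < _sigmoid(r_score + c0)
    else:
        readmit = np.zeros(n, dtype=bool)
    gaps = np.where(readmit, _draw_gaps(rng, n), np.nan)

    icu_discharge = rng.uniform(170.0, 260.0, n)
    hosp_discharge = icu_discharge + rng.uniform(12.0, 240.0, n)
    readmission_time = icu_discharge + gaps

    # stage-consistent creatinine/urine series, one substream per stay
    channel_order = ["creatinine", "urine_output", *VITAL_CHANNELS, *LAB_CHANNELS]
    channel_code = {c: i for i, c in enumerate(channel_order)}
    base_urine = 0.6 + 0.9 * _sigmoid(-1.2 * z[:, 7])
    stay_seeds = rng.integers(0, 2**31 - 1, size=n)
    obs_sid, obs_t, obs_v, obs_c = [], [], [], []
    for i in range(n):
        child = np.random.default_rng(stay_seeds[i])
        chans = _stage_channels(int(stage[i]), float(weight[i]),
                                config.urine_available, child,
                                config.obs_cadence, float(base_urine[i]))
        for cname, (t, v) in chans.items():
            obs_sid.append(np.full(t.size, i, dtype=np.int32))
            obs_t.append(t)
            obs_v.append(v)
            obs_c.append(np.full(t.size, channel_code[cname], dtype=np.int8))

    # vitals/labs vectorized across stays; per-stay level carries the latents
    for cname in VITAL_CHANNELS + LAB_CHANNELS:
        mean, sd, loadings = CHANNELS[cname]
        level = mean + sd * sum(w * z[:, j] for j, w in loadings.items())
        if cname in VITAL_CHANNELS:
            start, cad, span = 0.5, config.obs_cadence["vitals"], VITALS_SPAN_H
        else:
            start, cad, span = 6.0, config.obs_cadence["labs"], SERIES_SPAN_H
        base = np.arange(start, span, cad)
        m = base.size
        t = base[None, :] + rng.uniform(-0.2, 0.2, (n, m)) * cad
        t = np.clip(t, 0.05, None)
        v = level[:, None] + rng.normal(0.0, config.noise_sd * sd, (n, m))
        v = np.maximum(v, 0.0)
        obs_sid.append(np.repeat(np.arange(n, dtype=np.int32), m))
        obs_t.append(t.ravel())
        obs_v.append(v.ravel())
        obs_c.append(np.full(n * m, channel_code[cname], dtype=np.int8))

    sid_codes = np.concatenate(obs_sid)
    chan_codes = np.concatenate(obs_c)
    unit_order = [CHANNEL_UNITS[c] for c in channel_order]
    unit_levels = list(dict.fromkeys(unit_order))
    unit_codes = np.array([unit_levels.index(u) for u in unit_order],
                          dtype=np.int8)[chan_codes]
    observations = pd.DataFrame({
        "stay_id": pd.Categorical.from_codes(sid_codes, categories=stay_ids),
        "time_h": np.round(np.concatenate(obs_t), 3),
        "channel": pd.Categorical.from_codes(chan_codes, categories=channel_order),
        "value": np.round(np.concatenate(obs_v), 4),
        "units": pd.Categorical.from_codes(unit_codes, categories=unit_levels),
    })
    observations = observations.sort_values(
        ["stay_id", "channel", "time_h"], kind="stable").reset_index(drop=True)

    patients = pd.DataFrame({
        "patient_id": patient_ids, "ethnicity": ethnicity, "age_years": age,
        "sex": sex, "weight_kg": weight, "chronic_kidney_disease": ckd,
        **comorb,
    })
    stays = pd.DataFrame({
        "stay_id": stay_ids, "patient_id": patient_ids,
        "icu_admit_time": 0.0,
        "icu_discharge_time": np.round(icu_discharge, 2),
        "hospital_discharge_time": np.round(hosp_discharge, 2),
        "emr_epoch": epoch,
        "readmission_time": np.round(readmission_time, 2),
    })
    truth = pd.DataFrame({
        "stay_id": stay_ids,
        "true_aki_stage": stage,
        "true_readmission_gap_h": np.round(gaps, 2),
    })
    manifest = {"generator_version": GENERATOR_VERSION, "config": _config_dict(config)}
    return Cohort(patients, stays, observations, truth, manifest)


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    for key in ("ethnicity_mix", "epoch_mix", "stage_mix"):
        d[key] = [float(v) for v in d[key]]
    return d
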