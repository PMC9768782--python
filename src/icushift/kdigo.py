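"""KDIGO acute kidney injury staging from creatinine and urine-output series.

Assigns each ICU stay a stage in {0, 1, 2, 3} with an onset time and the
criterion that triggered it, following the KDIGO consensus rules:

creatinine arm (vs. a baseline creatinine)
    stage 1  value in [1.5, 2.0) x baseline, or a rise >= 0.3 mg/dL within
             any 48 h window
    stage 2  value in [2.0, 3.0) x baseline
    stage 3  value >= 3.0 x baseline, or an absolute value >= 4.0 mg/dL

urine arm (weight-normalized output rate, mL/kg/h)
    stage 1  rate < 0.5 sustained >= 6 h
    stage 2  rate < 0.5 sustained >= 12 h
    stage 3  rate < 0.3 sustained >= 24 h, or anuria (rate == 0) >= 12 h

The stay's stage is the maximum over both arms; the onset is the earliest
time at which that maximum stage's condition first holds.  Evaluation is
limited to the first 7 days of the stay, and the baseline creatinine is the
minimum value charted in the first 24 h (the cohort excludes admission AKI,
so early values approximate the pre-injury baseline).  Renal replacement
therapy, an alternative stage-3 trigger in the guideline, is out of scope:
the cohort schema carries no RRT channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, MissingBaselineError

# Staging windows (hours)
BASELINE_WINDOW_H = 24.0
EVALUATION_WINDOW_H = 168.0
DELTA_WINDOW_H = 48.0

# Creatinine thresholds (ratios are vs. baseline; absolute values in mg/dL)
RATIO_STAGE1 = 1.5
RATIO_STAGE2 = 2.0
RATIO_STAGE3 = 3.0
ABSOLUTE_STAGE3_MGDL = 4.0
DELTA48_MGDL = 0.3

# Urine thresholds (mL/kg/h) and sustained-span durations (hours)
URINE_RATE_STAGE12 = 0.5
URINE_RATE_STAGE3 = 0.3
URINE_HOURS_STAGE1 = 6.0
URINE_HOURS_STAGE2 = 12.0
URINE_HOURS_STAGE3 = 24.0
ANURIA_HOURS = 12.0
ANURIA_RATE = 1e-9
URINE_GAP_TOLERANCE_H = 2.0

# Criterion literals, in tie-break preference order within the creatinine arm
CRITERIA = (
    "creatinine_ratio",
    "creatinine_absolute",
    "creatinine_delta48",
    "urine_rate",
    "anuria",
)


@dataclass(frozen=True)
class ChannelSeries:
    """One charted channel for one stay (times in hours from ICU admission)."""

    stay_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    weight_kg: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape:
            raise InputError(f"{self.stay_id}/{self.channel}: times/values length mismatch")
        if t.size and np.any(np.diff(t) <= 0):
            raise InputError(f"{self.stay_id}/{self.channel}: times must be strictly increasing")
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise InputError(f"{self.stay_id}/{self.channel}: values must be finite and >= 0")


@dataclass(frozen=True)
class KdigoResult:
    """Per-stay staging outcome.  onset_time_h is None iff stage == 0."""

    stay_id: str
    stage: int
    onset_time_h: float | None
    criterion: str | None
    baseline_creatinine: float


def baseline_creatinine(series: ChannelSeries) -> float:
    """Minimum creatinine (mg/dL) charted in the first 24 h of the stay."""
    mask = series.times <= BASELINE_WINDOW_H
    if not mask.any():
        raise MissingBaselineError(
            f"{series.stay_id}: no creatinine in first {BASELINE_WINDOW_H:.0f} h"
        )
    value = float(series.values[mask].min())
    if value <= 0:
        raise InputError(f"{series.stay_id}: non-positive baseline creatinine")
    return value


def _truncate(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = times <= EVALUATION_WINDOW_H
    return times[keep], values[keep]


def stage_from_creatinine(
    series: ChannelSeries, baseline: float
) -> tuple[int, float | None, str | None]:
    """Creatinine-arm stage with the earliest onset of the maximum stage."""
    if baseline <= 0:
        raise InputError("baseline creatinine must be positive")
    times, values = _truncate(series.times, series.values)
    # events: (time, stage, criterion-preference-rank)
    events: list[tuple[float, int, int]] = []
    ratio = values / baseline
    for i, (t, v, r) in enumerate(zip(times, values, ratio)):
        if r >= RATIO_STAGE3:
            events.append((t, 3, 0))
        elif r >= RATIO_STAGE2:
            events.append((t, 2, 0))
        elif r >= RATIO_STAGE1:
            events.append((t, 1, 0))
        if v >= ABSOLUTE_STAGE3_MGDL:
            events.append((t, 3, 1))
        # rise >= 0.3 mg/dL vs. any earlier value within 48 h (inclusive ends)
        window = (times >= t - DELTA_WINDOW_H) & (times <= t)
        if window.any() and v - values[window].min() >= DELTA48_MGDL:
            events.append((t, 1, 2))
    if not events:
        return 0, None, None
    stage = max(s for _, s, _ in events)
    onset, _, rank = min((e for e in events if e[1] == stage), key=lambda e: (e[0], e[2]))
    return stage, onset, CRITERIA[rank]


def _urine_spans(
    times: np.ndarray, rates: np.ndarray, threshold: float, min_hours: float
) -> float | None:
    """Earliest time a sustained below-threshold span reaches min_hours.

    Each charted value covers the interval ending at its timestamp (the first
    value covers [0, t0]).  Intervals longer than the 2 h gap tolerance break
    a span and are never counted.
    """
    starts = np.concatenate([[0.0], times[:-1]])
    span_start = None
    accumulated = 0.0
    for start, end, rate in zip(starts, times, rates):
        length = end - start
        if length > URINE_GAP_TOLERANCE_H or rate >= threshold:
            span_start = None
            accumulated = 0.0
            continue
        if span_start is None:
            span_start = start
        accumulated += length
        if accumulated >= min_hours:
            return span_start + min_hours
    return None


def stage_from_urine(
    series: ChannelSeries, weight_kg: float
) -> tuple[int, float | None, str | None]:
    """Urine-arm stage from weight-normalized output rates."""
    if not (weight_kg > 0):
        raise InputError("weight_kg must be positive")
    if series.times.size == 0:
        return 0, None, None
    times, values = _truncate(series.times, series.values)
    if times.size == 0:
        return 0, None, None
    rates = values / weight_kg
    rules = (
        (3, ANURIA_RATE, ANURIA_HOURS, "anuria"),
        (3, URINE_RATE_STAGE3, URINE_HOURS_STAGE3, "urine_rate"),
        (2, URINE_RATE_STAGE12, URINE_HOURS_STAGE2, "urine_rate"),
        (1, URINE_RATE_STAGE12, URINE_HOURS_STAGE1, "urine_rate"),
    )
    best: tuple[int, float, str] | None = None
    for stage, threshold, hours, criterion in rules:
        onset = _urine_spans(times, rates, threshold, hours)
        if onset is None:
            continue
        if best is None or stage > best[0] or (stage == best[0] and onset < best[1]):
            best = (stage, onset, criterion)
    if best is None:
        return 0, None, None
    return best


def kdigo_stage(
    creatinine: ChannelSeries,
    urine: ChannelSeries | None,
    weight_kg: float,
) -> KdigoResult:
    """Combined stage: maximum over arms, earliest onset of that maximum.

    The urine arm is optional — with no urine series the creatinine arm
    stands alone.  Ties between arms at equal stage break to the earlier
    onset; equal onsets report the creatinine criterion.
    """
    baseline = baseline_creatinine(creatinine)
    arms = [stage_from_creatinine(creatinine, baseline)]
    if urine is not None and urine.times.size:
        arms.append(stage_from_urine(urine, weight_kg))
    stage = max(a[0] for a in arms)
    if stage == 0:
        return KdigoResult(creatinine.stay_id, 0, None, None, baseline)
    # creatinine arm listed first, so min() prefers it on exact onset ties
    onset, criterion = min(
        ((a[1], a[2]) for a in arms if a[0] == stage), key=lambda x: x[0]
    )
    return KdigoResult(creatinine.stay_id, stage, onset, criterion, baseline)


def label_cohort(observations: pd.DataFrame, stays: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Stage every stay in a cohort; one row per stay.

    Returns columns stay_id, stage, onset_time_h, criterion,
    baseline_creatinine, error.  Stays whose baseline cannot be computed get
    stage -1 and error 'missing_baseline' (downstream extraction drops them).
    """
    weight = patients.set_index("patient_id")["weight_kg"]
    stay_weight = stays.set_index("stay_id")["patient_id"].map(weight)
    rows = []
    obs = observations[observations["channel"].isin(["creatinine", "urine_output"])]
    obs = obs.sort_values(["stay_id", "channel", "time_h"])
    grouped = {k: g for k, g in obs.groupby("stay_id", observed=True, sort=False)}
    for stay_id in stays["stay_id"]:
        g = grouped.get(stay_id)
        w = float(stay_weight.get(stay_id, float("nan")))
        creat = urine = None
        if g is not None:
            for channel, gc in g.groupby("channel", observed=True):
                s = ChannelSeries(
                    str(stay_id), channel, gc["time_h"].to_numpy(float),
                    gc["value"].to_numpy(float), w,
                )
                if channel == "creatinine":
                    creat = s
                else:
                    urine = s
        if creat is None or not (creat.times <= BASELINE_WINDOW_H).any():
            rows.append((stay_id, -1, math.nan, None, math.nan, "missing_baseline"))
            continue
        res = kdigo_stage(creat, urine, w)
        rows.append(
            (stay_id, res.stage,
             math.nan if res.onset_time_h is None else res.onset_time_h,
             res.criterion, res.baseline_creatinine, None)
        )
    return pd.DataFrame(
        rows,
        columns=["stay_id", "stage", "onset_time_h", "criterion",
                 "baseline_creatinine", "error"],
    )
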