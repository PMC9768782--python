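"""AUROC, cohort I/O with schema validation, and run manifests.

AUROC is computed as the Mann-Whitney concordance probability: the fraction
of (positive, negative) pairs where the positive outscores the negative,
with ties earning half credit.  This is the probability interpretation of
the area under the ROC curve and is exactly what rank-based computation
yields; it is never silently defaulted to 0.5 when a class is missing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import SchemaError, UndefinedMetricError

logger = logging.getLogger("icushift")

ETHNICITY_LEVELS = ("White", "Black", "Latinx", "Other")
EPOCH_LEVELS = ("pre", "post", "crossover")
CHANNEL_UNITS = {
    "creatinine": "mg/dL",
    "urine_output": "mL/h",
    "heart_rate": "bpm",
    "systolic_bp": "mmHg",
    "diastolic_bp": "mmHg",
    "mean_bp": "mmHg",
    "respiration_rate": "breaths/min",
    "spo2": "%",
    "temperature": "degC",
    "bun": "mg/dL",
    "hemoglobin": "g/dL",
    "wbc": "K/uL",
    "sodium": "mEq/L",
    "potassium": "mEq/L",
    "glucose": "mg/dL",
}

_REQUIRED = {
    "patients": ["patient_id", "ethnicity", "age_years", "sex", "weight_kg"],
    "stays": ["stay_id", "patient_id", "icu_admit_time", "icu_discharge_time",
              "hospital_discharge_time", "emr_epoch", "readmission_time"],
    "observations": ["stay_id", "time_h", "channel", "value", "units"],
    "truth": ["stay_id", "true_aki_stage", "true_readmission_gap_h"],
}


def setup_logging(level: int = logging.INFO) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


@dataclass(frozen=True)
class MetricValue:
    name: str
    value: float
    n_pos: int
    n_neg: int
    tie_count: int


def auroc(scores, labels) -> MetricValue:
    """Mann-Whitney AUROC with half credit for tied pairs.

    Raises UndefinedMetricError unless both classes are present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise UndefinedMetricError("scores and labels must be equal-length 1-D vectors")
    y = y.astype(int)
    if not np.isin(y, [0, 1]).all():
        raise UndefinedMetricError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUROC undefined with n_pos={n_pos}, n_neg={n_neg}"
        )
    ranks = rankdata(s)  # average ranks implement the 0.5-credit tie convention
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    value = u / (n_pos * n_neg)
    # cross-class tied pairs, from tied-group composition
    ties = 0
    for _, grp in pd.Series(y).groupby(pd.Series(s)):
        kp = int(grp.sum())
        ties += kp * (len(grp) - kp)
    return MetricValue("auroc", float(value), n_pos, n_neg, int(ties))


def auroc_bootstrap_interval(scores, labels, n_boot: int = 400,
                             seed: int = 0, alpha: float = 0.05
                             ) -> tuple[float, float]:
    """Percentile bootstrap interval for AUROC (resampling test rows)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        idx = rng.integers(0, y.size, y.size)
        if y[idx].min() == y[idx].max():
            continue
        values.append(auroc(s[idx], y[idx]).value)
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Cohort I/O


def _check_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _REQUIRED[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required columns {missing}")


def validate_cohort_tables(
    patients: pd.DataFrame,
    stays: pd.DataFrame,
    observations: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> None:
    """Schema, vocabulary, range and referential-integrity checks."""
    _check_columns(patients, "patients")
    _check_columns(stays, "stays")
    _check_columns(observations, "observations")
    if truth is not None:
        _check_columns(truth, "truth")

    bad = ~patients["ethnicity"].isin(ETHNICITY_LEVELS)
    if bad.any():
        rows = patients.index[bad].tolist()[:5]
        raise SchemaError(f"patients: unknown ethnicity literal at rows {rows}")
    bad = ~stays["emr_epoch"].isin(EPOCH_LEVELS)
    if bad.any():
        rows = stays.index[bad].tolist()[:5]
        raise SchemaError(f"stays: unknown emr_epoch literal at rows {rows}")

    orphan = ~stays["patient_id"].isin(set(patients["patient_id"]))
    if orphan.any():
        rows = stays.index[orphan].tolist()[:5]
        raise SchemaError(f"stays: patient_id not in patients at rows {rows}")
    stay_ids = set(stays["stay_id"])
    orphan = ~observations["stay_id"].isin(stay_ids)
    if orphan.any():
        rows = observations.index[orphan].tolist()[:5]
        raise SchemaError(f"observations: stay_id not in stays at rows {rows}")
    if truth is not None:
        orphan = ~truth["stay_id"].isin(stay_ids)
        if orphan.any():
            rows = truth.index[orphan].tolist()[:5]
            raise SchemaError(f"truth: stay_id not in stays at rows {rows}")

    vals = observations["value"].to_numpy(float)
    if not np.isfinite(vals).all():
        rows = observations.index[~np.isfinite(vals)].tolist()[:5]
        raise SchemaError(f"observations: non-finite values at rows {rows}")
    if (vals < 0).any():
        rows = observations.index[vals < 0].tolist()[:5]
        raise SchemaError(f"observations: negative values at rows {rows}")
    bad = ~observations["units"].eq(observations["channel"].map(CHANNEL_UNITS))
    if bad.any():
        rows = observations.index[bad].tolist()[:5]
        raise SchemaError(f"observations: wrong units for channel at rows {rows}")

    if (stays["icu_admit_time"] >= stays["icu_discharge_time"]).any():
        raise SchemaError("stays: icu_admit_time must precede icu_discharge_time")
    readmit = stays["readmission_time"].dropna()
    if len(readmit):
        disch = stays.loc[readmit.index, "icu_discharge_time"]
        if (readmit <= disch).any():
            raise SchemaError("stays: readmission_time must follow icu_discharge_time")


def read_cohort(directory: str | Path):
    """Load and validate a cohort written by write_cohort.

    Returns a Cohort (see icushift.cohort).  Malformed tables raise
    SchemaError naming the offending rows.
    """
    from .cohort import Cohort  # local import to avoid a cycle

    directory = Path(directory)
    tables = {}
    for name in ("patients", "stays", "observations", "truth"):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing cohort table: {path}")
        tables[name] = pd.read_csv(path)
    manifest_path = directory / "manifest.yaml"
    manifest = {}
    if manifest_path.exists():
        import yaml

        manifest = yaml.safe_load(manifest_path.read_text())
    validate_cohort_tables(tables["patients"], tables["stays"],
                           tables["observations"], tables["truth"])
    return Cohort(tables["patients"], tables["stays"], tables["observations"],
                  tables["truth"], manifest)


def write_cohort(cohort, directory: str | Path) -> None:
    """Write the four cohort CSVs plus a YAML manifest."""
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(directory / "patients.csv", index=False)
    cohort.stays.to_csv(directory / "stays.csv", index=False)
    cohort.observations.to_csv(directory / "observations.csv", index=False)
    cohort.truth.to_csv(directory / "truth.csv", index=False)
    (directory / "manifest.yaml").write_text(yaml.safe_dump(cohort.manifest))


# ---------------------------------------------------------------------------
# Run manifests


def file_fingerprint(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    seeds,
    inputs: dict[str, str | Path] | None = None,
    row_counts: dict[str, int] | None = None,
) -> dict:
    """One manifest per CLI run: config snapshot, seeds, input fingerprints,
    per-stage row counts.  Sufficient to re-run bit-identically."""
    from . import __version__

    manifest = {
        "artifact_version": __version__,
        "command": command,
        "config": config,
        "seeds": list(np.asarray(seeds).tolist()) if seeds is not None else None,
        "input_fingerprints": {
            str(k): file_fingerprint(v) for k, v in (inputs or {}).items()
        },
        "row_counts": dict(row_counts or {}),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("wrote manifest %s", path)
    return manifest


def metric_to_dict(m: MetricValue) -> dict:
    return asdict(m)
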