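"""Deployment scenarios: baseline, drift, change of features, scarcity,
change of population, plus split-confounding diagnostics.

Each scenario is realized as a split-generation rule over an eligible cohort
followed by the same train/score/AUROC pipeline: features are summarized
from raw observations, imputation and normalization are fitted on training
rows only, a model is fitted on the training rows, and AUROC is measured on
the held-out side.  Stochastic scenarios run over a list of seeds and report
one result per seed (and per fraction / group / arm where applicable).

Split soundness is assertion-instrumented: train and test are disjoint by
construction, excluded stays never enter the feature matrix, and the
feature-matrix train flags are checked against the split before training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import kdigo
from .cohort import Cohort
from .errors import ConfigurationError, InfeasibleSplitError
from .features import (READMISSION_WINDOWS, build_features, extract_cohort,
                       readmission_labels)
from .metrics import auroc
from .models import (ModelSpec, TransferSpec, default_transfer_spec, fast_spec,
                     predict_proba, train, transfer_train)

SCENARIO_KINDS = ("baseline", "drift", "feature_change", "scarcity", "population")
DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario configuration (see module docstring)."""

    kind: str
    task: str = "aki_binary"
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    train_group: str = "White"
    test_groups: tuple[str, ...] = ("Black", "Latinx")
    include_urine: bool = True
    transfer: bool = True
    reference_auroc: float | None = None
    test_size: float = 0.2
    holdout_reference: bool = False
    fine_tune_epochs: int = 40

    def validate(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}")
        if not self.seeds:
            raise ConfigurationError("seeds must be non-empty")
        fr = np.asarray(self.fractions, dtype=float)
        if fr.size and (np.any(fr <= 0) or np.any(fr > 1) or np.any(np.diff(fr) <= 0)):
            raise ConfigurationError("fractions must be strictly increasing in (0, 1]")
        if self.kind == "population" and self.train_group in self.test_groups:
            raise ConfigurationError("train_group must differ from test_groups")


@dataclass
class SplitAssignment:
    """stay_id -> {train, test, excluded}, with a provenance note per exclusion."""

    assignment: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tags = set(self.assignment.unique())
        if not tags <= {"train", "test", "excluded"}:
            raise ConfigurationError(f"invalid split tags {tags}")
        assert not (set(self.train_ids) & set(self.test_ids))

    @property
    def train_ids(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "train"])

    @property
    def test_ids(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "test"])


def _assignment(ids, train_ids, test_ids, excluded: dict[str, str]) -> SplitAssignment:
    s = pd.Series("excluded", index=pd.Index(ids, name="stay_id"), dtype=object)
    s.loc[list(train_ids)] = "train"
    s.loc[list(test_ids)] = "test"
    return SplitAssignment(s, dict(excluded))


def split_baseline(eligible_ids, labels: pd.Series, seed: int,
                   test_size: float = 0.2) -> SplitAssignment:
    """Label-stratified random 80/20 split of the eligible stays."""
    ids = list(eligible_ids)
    y = np.asarray(labels.loc[ids])
    if len(ids) < 5 or min(np.bincount(pd.factorize(y)[0])) < 2:
        raise InfeasibleSplitError("too few stays per class to stratify")
    tr, te = train_test_split(ids, test_size=test_size, random_state=seed,
                              stratify=y)
    return _assignment(ids, tr, te, {})


def split_drift(stays: pd.DataFrame, eligible_ids) -> SplitAssignment:
    """Train on the pre-epoch stays, test on post; crossover stays excluded
    to keep the time cut-off clean."""
    epoch = stays.set_index("stay_id")["emr_epoch"].loc[list(eligible_ids)]
    train_ids = list(epoch.index[epoch == "pre"])
    test_ids = list(epoch.index[epoch == "post"])
    if not train_ids or not test_ids:
        raise InfeasibleSplitError("drift split needs stays in both epochs")
    excluded = {s: "crossover" for s in epoch.index[epoch == "crossover"]}
    return _assignment(list(eligible_ids), train_ids, test_ids, excluded)


def split_population(cohort: Cohort, eligible_ids, train_group: str,
                     test_group: str) -> SplitAssignment:
    """Train on one ethnicity group, test on another; everyone else excluded."""
    if train_group == test_group:
        raise ConfigurationError("degenerate transfer: train_group == test_group")
    eth = _ethnicity(cohort).loc[list(eligible_ids)]
    train_ids = list(eth.index[eth == train_group])
    test_ids = list(eth.index[eth == test_group])
    if not train_ids or not test_ids:
        raise InfeasibleSplitError(
            f"population split needs stays in {train_group} and {test_group}")
    excluded = {s: "out_of_group" for s in eth.index
                if eth.loc[s] not in (train_group, test_group)}
    return _assignment(list(eligible_ids), train_ids, test_ids, excluded)


def _ethnicity(cohort: Cohort) -> pd.Series:
    pat = cohort.patients.set_index("patient_id")["ethnicity"]
    s = cohort.stays.set_index("stay_id")["patient_id"].map(pat)
    s.name = "ethnicity"
    return s


def prepare_task(cohort: Cohort, task: str):
    """Label the cohort, apply exclusions, and build the task label series."""
    labels_df = kdigo.label_cohort(cohort.observations, cohort.stays,
                                   cohort.patients)
    eligible, exclusions = extract_cohort(cohort, labels_df)
    if task == "aki_binary":
        y = (labels_df.set_index("stay_id")["stage"] >= 1).astype(int)
    elif task.startswith("readmission_"):
        window = task.removeprefix("readmission_")
        if window not in READMISSION_WINDOWS:
            raise ConfigurationError(f"unknown readmission window {window!r}")
        rl = readmission_labels(cohort.stays).set_index("stay_id")
        y = rl[window].astype(int)
    else:
        raise ConfigurationError(f"unknown task {task!r}")
    return labels_df, eligible, exclusions, y


def _fit_and_score(cohort, y, train_ids, test_sets: dict, model_spec,
                   include_urine, seed, excluded_ids=()):
    """One model fit on train_ids, AUROC on each named test set."""
    test_all = [s for ids in test_sets.values() for s in ids]
    rows = list(dict.fromkeys([*train_ids, *test_all]))
    assert not (set(train_ids) & set(test_all)), "train/test overlap"
    assert not (set(rows) & set(excluded_ids)), "excluded stay reached the pipeline"
    fm = build_features(cohort, rows, include_urine=include_urine,
                        train_ids=train_ids)
    assert set(np.asarray(fm.stay_ids)[fm.train_mask]) == set(train_ids)
    spec = dataclasses.replace(model_spec, seed=seed)
    model = train(fm, y.loc[fm.stay_ids].to_numpy(), spec)
    scores = predict_proba(model, fm)
    pos = pd.Series(np.arange(len(fm.stay_ids)), index=fm.stay_ids)
    out = {}
    raw = {}
    for name, ids in test_sets.items():
        idx = pos.loc[list(ids)].to_numpy()
        y_test = y.loc[list(ids)].to_numpy()
        m = auroc(scores[idx], y_test)
        out[name] = (m.value, len(train_ids), len(ids))
        raw[name] = (scores[idx], y_test)
    return out, model, fm, raw


def _stratified_fraction(ids, y, fraction, seed):
    ids = list(ids)
    if fraction >= 1.0:
        return ids
    yy = np.asarray(y.loc[ids])
    n = max(int(round(fraction * len(ids))), 2)
    if n >= len(ids):
        return ids
    sub, _ = train_test_split(ids, train_size=n, random_state=seed, stratify=yy)
    return sub


def run_scenario(spec: ScenarioSpec, cohort: Cohort,
                 model_spec: ModelSpec | None = None,
                 return_predictions: bool = False):
    """Execute one scenario; one result row per seed x fraction/group/arm.

    With return_predictions=True also returns a list aligned with the result
    rows holding each row's held-out (scores, labels) pair.
    """
    spec.validate()
    if model_spec is None:
        model_spec = fast_spec(task=spec.task)
    _, eligible, _, y = prepare_task(cohort, spec.task)
    results = []
    predictions = []

    def emit(seed, scored, raw=None, *, fraction=None, arm=None, group=None):
        for name, (value, n_train, n_test) in scored.items():
            results.append({
                "scenario": spec.kind, "task": spec.task, "seed": seed,
                "arm": arm, "fraction": fraction, "group_pair": group,
                "auroc": value, "n_train": n_train, "n_test": n_test,
            })
            predictions.append(None if raw is None else raw.get(name))

    for seed in spec.seeds:
        if spec.kind == "baseline":
            split = split_baseline(eligible, y, seed, spec.test_size)
            scored, _, _, raw = _fit_and_score(
                cohort, y, split.train_ids, {"test": split.test_ids},
                model_spec, spec.include_urine, seed)
            emit(seed, scored, raw)

        elif spec.kind == "drift":
            split = split_drift(cohort.stays, eligible)
            scored, _, _, raw = _fit_and_score(
                cohort, y, split.train_ids, {"test": split.test_ids},
                model_spec, spec.include_urine, seed,
                excluded_ids=list(split.provenance))
            emit(seed, scored, raw)

        elif spec.kind == "population":
            eth = _ethnicity(cohort).loc[eligible]
            group_ids = {g: list(eth.index[eth == g])
                         for g in (spec.train_group, *spec.test_groups)}
            for g, ids in group_ids.items():
                if not ids:
                    raise InfeasibleSplitError(f"no eligible stays in group {g}")
            if spec.holdout_reference:
                tr, holdout = train_test_split(
                    group_ids[spec.train_group], test_size=spec.test_size,
                    random_state=seed,
                    stratify=np.asarray(y.loc[group_ids[spec.train_group]]))
                test_sets = {f"{spec.train_group}-{spec.train_group}": holdout}
            else:
                tr = group_ids[spec.train_group]
                test_sets = {}
            test_sets.update({f"{spec.train_group}-{g}": group_ids[g]
                              for g in spec.test_groups})
            scored, _, _, raw = _fit_and_score(cohort, y, tr, test_sets,
                                               model_spec, spec.include_urine,
                                               seed)
            for name, triple in scored.items():
                emit(seed, {name: triple}, {name: raw[name]}, group=name)

        elif spec.kind == "scarcity":
            for fraction in spec.fractions:
                if fraction >= 1.0:
                    continue  # no remainder to test on
                tr, te = train_test_split(
                    list(eligible), train_size=fraction, random_state=seed,
                    stratify=np.asarray(y.loc[eligible]))
                scored, _, _, raw = _fit_and_score(
                    cohort, y, tr, {"test": te}, model_spec,
                    spec.include_urine, seed)
                emit(seed, scored, raw, fraction=fraction)

        elif spec.kind == "feature_change":
            split = split_baseline(eligible, y, seed, spec.test_size)
            tr_full, te = split.train_ids, split.test_ids
            base_scored, base_model, _, base_raw = _fit_and_score(
                cohort, y, tr_full, {"test": te}, model_spec, False, seed)
            for fraction in spec.fractions:
                sub = _stratified_fraction(tr_full, y, fraction, seed)
                no_ur, _, _, raw = _fit_and_score(cohort, y, sub, {"test": te},
                                                  model_spec, False, seed)
                emit(seed, no_ur, raw, fraction=fraction, arm="no_urine")
                scratch, _, _, raw = _fit_and_score(cohort, y, sub,
                                                    {"test": te}, model_spec,
                                                    True, seed)
                emit(seed, scratch, raw, fraction=fraction,
                     arm="with_urine_scratch")
                if spec.transfer:
                    tscored, traw = _transfer_eval(cohort, y, base_model, sub,
                                                   te, spec, seed)
                    emit(seed, tscored, traw, fraction=fraction,
                         arm="with_urine_transfer")
            emit(seed, base_scored, base_raw, fraction=1.0,
                 arm="no_urine_full_reference")

    df = pd.DataFrame(results)
    if return_predictions:
        return df, predictions
    return df


def _transfer_eval(cohort, y, base_model, train_ids, test_ids, spec, seed):
    rows = list(dict.fromkeys([*train_ids, *test_ids]))
    fm = build_features(cohort, rows, include_urine=True, train_ids=train_ids)
    tspec = default_transfer_spec(len(base_model.spec.hidden_layers), seed=seed,
                                  fine_tune_epochs=spec.fine_tune_epochs)
    model = transfer_train(base_model, fm, y.loc[fm.stay_ids].to_numpy(), tspec)
    scores = predict_proba(model, fm)
    pos = pd.Series(np.arange(len(fm.stay_ids)), index=fm.stay_ids)
    idx = pos.loc[list(test_ids)].to_numpy()
    y_test = y.loc[list(test_ids)].to_numpy()
    m = auroc(scores[idx], y_test)
    return ({"test": (m.value, len(train_ids), len(test_ids))},
            {"test": (scores[idx], y_test)})


# ---------------------------------------------------------------------------
# Aggregation


def learning_curve(results: pd.DataFrame) -> pd.DataFrame:
    """fraction -> (mean AUROC, sd over seeds, mean n_train)."""
    df = results.dropna(subset=["fraction"])
    out = df.groupby("fraction").agg(
        mean_auroc=("auroc", "mean"), sd_auroc=("auroc", "std"),
        n_train=("n_train", "mean"), n_seeds=("auroc", "size"),
    ).reset_index()
    out["sd_auroc"] = out["sd_auroc"].fillna(0.0)
    return out


def crossover_fraction(curve: pd.DataFrame, reference_auroc: float) -> float | None:
    """Smallest grid fraction whose mean AUROC reaches the reference."""
    curve = curve.sort_values("fraction")
    hit = curve[curve["mean_auroc"] >= reference_auroc]
    if hit.empty:
        return None
    return float(hit["fraction"].iloc[0])


def confounding_table(cohort: Cohort, partition_a, partition_b,
                      b_levels=None) -> pd.DataFrame:
    """Percentage of each B-level within each A-level and in the whole cohort.

    Partitions are stay-indexed Series (or 'ethnicity' / 'emr_epoch' column
    names).  Percentages are relative to the A-level row count, so B-levels
    omitted from b_levels (e.g. a crossover epoch) make rows sum to < 100 %.
    """
    a = _resolve_partition(cohort, partition_a)
    b = _resolve_partition(cohort, partition_b)
    b = b.loc[a.index]
    if b_levels is None:
        b_levels = list(pd.unique(b))
    rows = {}
    rows["whole_dataset"] = [100.0 * float((b == lv).mean()) for lv in b_levels]
    for level in pd.unique(a):
        mask = a == level
        rows[str(level)] = [100.0 * float((b[mask] == lv).mean()) for lv in b_levels]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[str(lv) for lv in b_levels])


def _resolve_partition(cohort: Cohort, partition) -> pd.Series:
    if isinstance(partition, pd.Series):
        return partition
    if partition == "ethnicity":
        return _ethnicity(cohort)
    if partition == "ethnicity_white_other":
        eth = _ethnicity(cohort)
        return eth.where(eth == "White", "Other")
    if partition == "emr_epoch":
        return cohort.stays.set_index("stay_id")["emr_epoch"]
    raise ConfigurationError(f"unknown partition {partition!r}")
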