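"""Multilayer-perceptron predictors with layer-freezing transfer learning.

The network is implemented directly in NumPy because the transfer procedure
needs exact control over individual layers: frozen hidden layers must keep
their parameters bitwise unchanged while the widened input layer and the
remaining layers fine-tune on the new data.  Architecture: fully connected
ReLU hidden layers, softmax output, class-weighted cross-entropy (so AUROC
is estimated at the natural prevalence rather than after resampling), Adam
updates, mini-batches, optional L2 penalty, and early stopping on a
stratified validation split.  Everything stochastic — initialization, batch
order, validation split, fold assignment — is driven by the spec seed, so
identical (data, spec, seed) reproduce identical parameters.

The default AKI architecture is a 15-hidden-layer tapering stack; the depth
is a fixed design choice of the AKI predictor being studied, with the widths
and optimizer settings fixed here.  Scenario experiments accept any
ModelSpec, and a compact 2-layer spec is provided for fast evaluation runs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import (ConfigurationError, DegenerateTaskError, InputError,
                     InterfaceError)
from .features import FeatureMatrix
from .metrics import auroc


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters."""

    hidden_layers: tuple[int, ...] = (32, 16)
    activation: str = "relu"
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    l2: float = 1e-4
    seed: int = 0
    task: str = "aki_binary"
    val_fraction: float = 0.1
    class_weighted: bool = True

    def validate(self) -> None:
        if len(self.hidden_layers) < 1 or any(w < 1 for w in self.hidden_layers):
            raise ConfigurationError("hidden_layers must be >=1 positive widths")
        if self.activation != "relu":
            raise ConfigurationError("only relu activation is supported")
        if not 0 <= self.val_fraction < 0.5:
            raise ConfigurationError("val_fraction must be in [0, 0.5)")


def aki_default_spec(seed: int = 0) -> ModelSpec:
    """The 15-hidden-layer tapering AKI architecture."""
    widths = (96, 96, 80, 80, 64, 64, 48, 48, 40, 32, 32, 24, 16, 12, 8)
    return ModelSpec(hidden_layers=widths, max_epochs=150, patience=15, seed=seed)


def fast_spec(seed: int = 0, task: str = "aki_binary") -> ModelSpec:
    """Compact spec for scenario sweeps and tests."""
    return ModelSpec(hidden_layers=(24, 12), learning_rate=3e-3, batch_size=256,
                     max_epochs=60, patience=8, seed=seed, task=task)


@dataclass(frozen=True)
class TransferSpec:
    """How to adapt a trained model to a widened feature set.

    frozen_layers are 1-based hidden-layer indices; they must form a
    non-empty strict subset of the hidden layers.  New input weights are
    zero-initialized so the widened model is exactly the old model before
    fine-tuning.
    """

    frozen_layers: tuple[int, ...]
    fine_tune_epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 128
    seed: int = 0
    new_weight_init: str = "zero"


def default_transfer_spec(depth: int, seed: int = 0, fine_tune_epochs: int = 30
                          ) -> TransferSpec:
    """Freeze hidden layers 2..depth-1 (the last hidden layer for depth 2),
    leaving the widened input layer and the output layer free to adapt."""
    if depth < 2:
        raise ConfigurationError("transfer requires >= 2 hidden layers")
    frozen = tuple(range(2, depth)) if depth >= 3 else (2,)
    return TransferSpec(frozen_layers=frozen, seed=seed,
                        fine_tune_epochs=fine_tune_epochs)


@dataclass
class TrainedModel:
    """Opaque parameter state plus everything needed to apply it safely."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: np.ndarray
    feature_names: list[str]
    medians: np.ndarray
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    spec: ModelSpec
    manifest: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return len(self.weights) - 1


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, biases, x):
    acts = [x]
    h = x
    for w, b in zip(weights[:-1], biases[:-1]):
        h = np.maximum(h @ w + b, 0.0)
        acts.append(h)
    logits = h @ weights[-1] + biases[-1]
    return acts, logits


def _init_params(rng, widths):
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _sample_weights(y_idx: np.ndarray, n_classes: int, balanced: bool) -> np.ndarray:
    if not balanced:
        return np.ones(y_idx.size)
    counts = np.bincount(y_idx, minlength=n_classes)
    w = y_idx.size / (n_classes * np.maximum(counts, 1))
    return w[y_idx]


def _weighted_loss(weights, biases, x, y_idx, sw, l2, trainable) -> float:
    _, logits = _forward(weights, biases, x)
    p = _softmax(logits)
    nll = -np.log(np.maximum(p[np.arange(y_idx.size), y_idx], 1e-12))
    loss = float((sw * nll).sum() / sw.sum())
    if l2:
        loss += l2 * sum(float((w ** 2).sum()) for i, w in enumerate(weights)
                         if trainable[i])
    return loss


def _fit(weights, biases, x, y_idx, n_classes, *, rng, sw, learning_rate,
         batch_size, max_epochs, patience, l2, val, trainable) -> None:
    """Adam mini-batch training in place; layers with trainable[i] False are
    never touched (no update, no weight decay)."""
    n_layers = len(weights)
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best = None
    best_loss = np.inf
    stall = 0
    for _ in range(max_epochs):
        order = rng.permutation(x.shape[0])
        for start in range(0, x.shape[0], batch_size):
            idx = order[start:start + batch_size]
            xb, yb, wb = x[idx], y_idx[idx], sw[idx]
            acts, logits = _forward(weights, biases, xb)
            p = _softmax(logits)
            delta = p
            delta[np.arange(yb.size), yb] -= 1.0
            delta *= (wb / wb.sum())[:, None]
            step += 1
            corr1 = 1 - beta1 ** step
            corr2 = 1 - beta2 ** step
            for layer in range(n_layers - 1, -1, -1):
                grad_w = acts[layer].T @ delta
                grad_b = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (acts[layer] > 0)
                if not trainable[layer]:
                    continue
                if l2:
                    grad_w = grad_w + 2.0 * l2 * weights[layer]
                m_w[layer] = beta1 * m_w[layer] + (1 - beta1) * grad_w
                v_w[layer] = beta2 * v_w[layer] + (1 - beta2) * grad_w ** 2
                m_b[layer] = beta1 * m_b[layer] + (1 - beta1) * grad_b
                v_b[layer] = beta2 * v_b[layer] + (1 - beta2) * grad_b ** 2
                weights[layer] -= learning_rate * (m_w[layer] / corr1) / (
                    np.sqrt(v_w[layer] / corr2) + eps)
                biases[layer] -= learning_rate * (m_b[layer] / corr1) / (
                    np.sqrt(v_b[layer] / corr2) + eps)
        if val is not None:
            xv, yv, wv = val
            loss = _weighted_loss(weights, biases, xv, yv, wv, 0.0, trainable)
            if loss < best_loss - 1e-6:
                best_loss = loss
                best = ([w.copy() for w in weights], [b.copy() for b in biases])
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
    if best is not None:
        for layer in range(n_layers):
            if trainable[layer]:
                weights[layer][...] = best[0][layer]
                biases[layer][...] = best[1][layer]


def _prepare_labels(labels, train_mask):
    y = np.asarray(labels)
    classes = np.unique(y[train_mask])
    if classes.size < 2:
        raise DegenerateTaskError("training labels contain a single class")
    lookup = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([lookup.get(v, -1) for v in y])
    return y_idx, classes


def train(features: FeatureMatrix, labels, spec: ModelSpec) -> TrainedModel:
    """Fit an MLP on the rows flagged train in the feature matrix.

    Rows flagged test are never touched: not by normalization (fitted by the
    FeatureMatrix), not by training, not by early stopping.
    """
    spec.validate()
    y_all = np.asarray(labels)
    if y_all.shape[0] != len(features.stay_ids):
        raise InputError("labels must align with feature-matrix rows")
    y_idx_all, classes = _prepare_labels(y_all, features.train_mask)
    x_all = features.design_matrix()
    x = x_all[features.train_mask]
    y_idx = y_idx_all[features.train_mask]

    rng = np.random.default_rng(spec.seed)
    val = None
    min_class = np.bincount(y_idx).min()
    if spec.val_fraction > 0 and x.shape[0] >= 40 and min_class >= 4:
        tr, va = train_test_split(
            np.arange(x.shape[0]), test_size=spec.val_fraction,
            random_state=spec.seed, stratify=y_idx)
        sw_val = _sample_weights(y_idx[va], classes.size, spec.class_weighted)
        val = (x[va], y_idx[va], sw_val)
        x, y_idx = x[tr], y_idx[tr]

    widths = [x.shape[1], *spec.hidden_layers, classes.size]
    weights, biases = _init_params(rng, widths)
    sw = _sample_weights(y_idx, classes.size, spec.class_weighted)
    trainable = [True] * len(weights)
    _fit(weights, biases, x, y_idx, classes.size, rng=rng, sw=sw,
         learning_rate=spec.learning_rate, batch_size=spec.batch_size,
         max_epochs=spec.max_epochs, patience=spec.patience, l2=spec.l2,
         val=val, trainable=trainable)
    manifest = {"spec": asdict(spec), "n_train": int(features.train_mask.sum()),
                "n_features": x.shape[1], "classes": classes.tolist()}
    return TrainedModel(weights, biases, classes, list(features.feature_names),
                        features.medians.copy(), features.norm_mean.copy(),
                        features.norm_sd.copy(), spec, manifest)


def _model_design(model: TrainedModel, features) -> np.ndarray:
    """Impute and normalize raw features with the *model's* stored parameters,
    refusing any column mismatch (no silent reordering)."""
    if isinstance(features, FeatureMatrix):
        if list(features.feature_names) != list(model.feature_names):
            raise InterfaceError(
                "feature names/order do not match the model's; refusing to reorder")
        raw = features.values
    else:
        raw = np.asarray(features, dtype=float)
        if raw.ndim != 2 or raw.shape[1] != len(model.feature_names):
            raise InterfaceError("feature matrix width does not match the model")
    imputed = np.where(np.isnan(raw), model.medians, raw)
    return (imputed - model.norm_mean) / model.norm_sd


def predict_proba_full(model: TrainedModel, features) -> np.ndarray:
    x = _model_design(model, features)
    _, logits = _forward(model.weights, model.biases, x)
    return _softmax(logits)


def predict_proba(model: TrainedModel, features) -> np.ndarray:
    """Probability of the positive (largest) class, row order preserved."""
    p = predict_proba_full(model, features)
    return p[:, -1] if p.shape[1] == 2 else p[:, -1]


def hyperparameter_search(features: FeatureMatrix, labels, grid,
                          k_folds: int = 5, seed: int = 0
                          ) -> tuple[ModelSpec, list[dict]]:
    """Grid search by mean stratified-k-fold AUROC on the training rows.

    Returns (best spec, per-point log with fold assignments and scores).
    Ties break to the earlier grid point.
    """
    grid = list(grid)
    if not grid:
        raise ConfigurationError("hyperparameter grid is empty")
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    y_all = np.asarray(labels)
    train_rows = np.flatnonzero(features.train_mask)
    y = y_all[train_rows]
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(train_rows, y))
    log: list[dict] = []
    best_spec, best_score = None, -np.inf
    for spec in grid:
        scores = []
        for fold_id, (tr, va) in enumerate(folds):
            fold_fm = FeatureMatrix(
                features.stay_ids, features.feature_names, features.values,
                features.urine_group,
                np.isin(np.arange(len(features.stay_ids)), train_rows[tr]))
            model = train(fold_fm, y_all, spec)
            p = predict_proba(model, features)[train_rows[va]]
            scores.append(auroc(p, (y_all[train_rows[va]] ==
                                    model.classes[-1]).astype(int)).value)
        mean_score = float(np.mean(scores))
        log.append({"spec": asdict(spec), "fold_auroc": scores,
                    "mean_auroc": mean_score,
                    "folds": [tr.tolist() for tr, _ in folds]})
        if mean_score > best_score:
            best_spec, best_score = spec, mean_score
    return best_spec, log


def transfer_train(old_model: TrainedModel, features: FeatureMatrix, labels,
                   tspec: TransferSpec) -> TrainedModel:
    """Adapt old_model to a widened feature set by layer freezing.

    The input layer is widened: weights of old features are copied, weights
    of new features start at zero (so with zero fine-tune epochs the model
    *is* the old model).  Hidden layers listed in tspec.frozen_layers keep
    their parameters bitwise; everything else fine-tunes on the training rows.
    """
    depth = old_model.depth
    frozen = set(tspec.frozen_layers)
    if not frozen or not frozen < set(range(1, depth + 1)):
        raise ConfigurationError(
            "frozen_layers must be a non-empty strict subset of hidden layers "
            f"1..{depth}")
    if tspec.new_weight_init != "zero":
        raise ConfigurationError("only zero initialization of new weights is supported")
    old_names = list(old_model.feature_names)
    new_names = list(features.feature_names)
    if set(old_names) & set(new_names) != set(old_names):
        raise InterfaceError("old feature set must be a subset of the new one")
    added = [c for c in new_names if c not in set(old_names)]
    if not added:
        raise ConfigurationError("no new features: nothing to transfer to")

    pos = {c: i for i, c in enumerate(new_names)}
    old_pos = np.array([pos[c] for c in old_names])
    new_pos = np.array([pos[c] for c in added])

    n_in = len(new_names)
    w0 = np.zeros((n_in, old_model.weights[0].shape[1]))
    w0[old_pos] = old_model.weights[0]
    weights = [w0] + [w.copy() for w in old_model.weights[1:]]
    biases = [b.copy() for b in old_model.biases]

    # per-feature preprocessing: old features keep the old model's parameters
    # exactly (zero-epoch identity); new features take theirs from `features`
    medians = features.medians.copy()
    norm_mean = features.norm_mean.copy()
    norm_sd = features.norm_sd.copy()
    medians[old_pos] = old_model.medians
    norm_mean[old_pos] = old_model.norm_mean
    norm_sd[old_pos] = old_model.norm_sd

    y_all = np.asarray(labels)
    y_idx_all, classes = _prepare_labels(y_all, features.train_mask)
    if not np.array_equal(classes, old_model.classes):
        raise DegenerateTaskError("transfer training classes differ from the old model's")

    model = TrainedModel(weights, biases, classes, new_names, medians,
                         norm_mean, norm_sd, old_model.spec,
                         {"transfer": asdict(tspec),
                          "n_train": int(features.train_mask.sum())})
    if tspec.fine_tune_epochs > 0:
        x = _model_design(model, features)[features.train_mask]
        y_idx = y_idx_all[features.train_mask]
        sw = _sample_weights(y_idx, classes.size, old_model.spec.class_weighted)
        trainable = [i + 1 not in frozen for i in range(len(weights))]
        trainable[-1] = True  # output layer always adapts
        rng = np.random.default_rng(tspec.seed)
        _fit(weights, biases, x, y_idx, classes.size, rng=rng, sw=sw,
             learning_rate=tspec.learning_rate, batch_size=tspec.batch_size,
             max_epochs=tspec.fine_tune_epochs, patience=tspec.fine_tune_epochs,
             l2=0.0, val=None, trainable=trainable)
    return model
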