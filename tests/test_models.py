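"""MLP training contracts: fit quality, determinism, interface safety,
hyperparameter search, and the layer-freezing transfer procedure."""

import numpy as np
import pytest

import icushift as ic
from icushift.features import FeatureMatrix


def matrix(x, names=None, train_mask=None):
    names = names or [f"f{i}" for i in range(x.shape[1])]
    mask = np.ones(x.shape[0], dtype=bool) if train_mask is None else train_mask
    return FeatureMatrix([f"s{i}" for i in range(x.shape[0])], names,
                         np.asarray(x, float), (), mask)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(400, 2))
    y = (x[:, 0] + x[:, 1] > 0).astype(int)
    x[y == 1] += 1.5  # wide margin
    return matrix(x), y


def test_separable_data_fits_nearly_perfectly(separable):
    fm, y = separable
    model = ic.train(fm, y, ic.ModelSpec(hidden_layers=(8, 4), max_epochs=80,
                                         seed=0))
    p = ic.predict_proba(model, fm)
    assert ic.auroc(p, y).value >= 0.99


def test_permuted_labels_score_at_chance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2000, 10))
    y = rng.integers(0, 2, 2000)  # labels independent of features
    mask = np.zeros(2000, dtype=bool)
    mask[:1600] = True
    fm = matrix(x, train_mask=mask)
    model = ic.train(fm, y, ic.fast_spec(seed=0))
    p = ic.predict_proba(model, fm)[~mask]
    assert 0.45 <= ic.auroc(p, y[~mask]).value <= 0.55


def test_seeded_determinism(separable):
    fm, y = separable
    spec = ic.ModelSpec(hidden_layers=(8, 4), max_epochs=20, seed=5)
    a = ic.train(fm, y, spec)
    b = ic.train(fm, y, spec)
    for wa, wb in zip(a.weights, b.weights):
        np.testing.assert_array_equal(wa, wb)


def test_probabilities_sum_to_one(separable):
    fm, y = separable
    model = ic.train(fm, y, ic.ModelSpec(hidden_layers=(4,), max_epochs=5))
    p = ic.predict_proba_full(model, fm)
    assert np.all(p >= 0) and np.all(p <= 1)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_single_class_labels_rejected(separable):
    fm, _ = separable
    with pytest.raises(ic.DegenerateTaskError):
        ic.train(fm, np.zeros(len(fm.stay_ids)), ic.ModelSpec())


def test_column_mismatch_refused(separable):
    fm, y = separable
    model = ic.train(fm, y, ic.ModelSpec(hidden_layers=(4,), max_epochs=5))
    swapped = matrix(fm.values[:, ::-1], names=list(fm.feature_names[::-1]))
    with pytest.raises(ic.InterfaceError):
        ic.predict_proba(model, swapped)


def test_training_never_touches_test_rows():
    """Moving test-row values must not change the fitted parameters."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=(300, 5))
    y = (x[:, 0] > 0).astype(int)
    mask = np.zeros(300, dtype=bool)
    mask[:200] = True
    spec = ic.ModelSpec(hidden_layers=(6,), max_epochs=15, seed=2)
    a = ic.train(matrix(x, train_mask=mask), y, spec)
    x2 = x.copy()
    x2[~mask] += 100.0
    b = ic.train(matrix(x2, train_mask=mask), y, spec)
    for wa, wb in zip(a.weights, b.weights):
        np.testing.assert_array_equal(wa, wb)


class TestHyperparameterSearch:
    def test_singleton_grid_returned(self, separable):
        fm, y = separable
        spec = ic.ModelSpec(hidden_layers=(4,), max_epochs=5)
        best, log = ic.hyperparameter_search(fm, y, [spec], k_folds=3, seed=0)
        assert best is spec and len(log) == 1

    def test_fold_assignment_reproducible(self, separable):
        fm, y = separable
        spec = ic.ModelSpec(hidden_layers=(4,), max_epochs=5)
        _, log_a = ic.hyperparameter_search(fm, y, [spec], k_folds=3, seed=9)
        _, log_b = ic.hyperparameter_search(fm, y, [spec], k_folds=3, seed=9)
        assert log_a[0]["folds"] == log_b[0]["folds"]

    def test_capacity_wins_on_xor_task(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1200, 2))
        y = ((x[:, 0] > 0) ^ (x[:, 1] > 0)).astype(int)  # no linear signal
        fm = matrix(x)
        narrow = ic.ModelSpec(hidden_layers=(1,), max_epochs=60, seed=0,
                              learning_rate=3e-3)
        deep = ic.ModelSpec(hidden_layers=(16, 16, 8, 8), max_epochs=60,
                            seed=0, learning_rate=3e-3)
        best, log = ic.hyperparameter_search(fm, y, [narrow, deep],
                                             k_folds=3, seed=0)
        assert best is deep
        assert log[1]["mean_auroc"] > log[0]["mean_auroc"] + 0.2

    def test_empty_grid_rejected(self, separable):
        fm, y = separable
        with pytest.raises(ic.ConfigurationError):
            ic.hyperparameter_search(fm, y, [], seed=0)


@pytest.fixture(scope="module")
def transfer_setup():
    rng = np.random.default_rng(7)
    n = 900
    x_old = rng.normal(size=(n, 4))
    x_new_feat = rng.normal(size=(n, 2))
    logit = x_old @ [1.0, -0.8, 0.6, 0.0] + x_new_feat @ [1.2, -1.0]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    old_fm = matrix(x_old, names=["a", "b", "c", "d"])
    new_names = ["a", "b", "u1", "c", "d", "u2"]
    x_all = np.column_stack([x_old[:, 0], x_old[:, 1], x_new_feat[:, 0],
                             x_old[:, 2], x_old[:, 3], x_new_feat[:, 1]])
    new_fm = matrix(x_all, names=new_names)
    spec = ic.ModelSpec(hidden_layers=(12, 8), max_epochs=40, seed=0,
                        learning_rate=3e-3)
    old_model = ic.train(old_fm, y, spec)
    return old_model, old_fm, new_fm, y


class TestTransfer:
    @pytest.fixture()
    def setup(self, transfer_setup):
        return transfer_setup

    def test_zero_finetune_is_identity_on_old_features(self, setup):
        old_model, old_fm, new_fm, y = setup
        tspec = ic.TransferSpec(frozen_layers=(2,), fine_tune_epochs=0)
        widened = ic.transfer_train(old_model, new_fm, y, tspec)
        np.testing.assert_allclose(ic.predict_proba(widened, new_fm),
                                   ic.predict_proba(old_model, old_fm),
                                   atol=1e-12)

    def test_frozen_layers_bitwise_unchanged(self, setup):
        old_model, _, new_fm, y = setup
        tspec = ic.TransferSpec(frozen_layers=(2,), fine_tune_epochs=10, seed=1)
        widened = ic.transfer_train(old_model, new_fm, y, tspec)
        # hidden layer 2 = weights[1]: bitwise identical
        np.testing.assert_array_equal(widened.weights[1], old_model.weights[1])
        np.testing.assert_array_equal(widened.biases[1], old_model.biases[1])
        # unfrozen layers moved
        assert not np.array_equal(widened.weights[2], old_model.weights[2])
        assert not np.array_equal(
            widened.weights[0][[0, 1, 3, 4]], old_model.weights[0])

    def test_new_features_must_not_overlap(self, setup):
        old_model, old_fm, _, y = setup
        with pytest.raises(ic.ConfigurationError, match="nothing to transfer"):
            ic.transfer_train(old_model, old_fm, y,
                              ic.TransferSpec(frozen_layers=(2,)))

    def test_frozen_set_must_be_strict_subset(self, setup):
        old_model, _, new_fm, y = setup
        with pytest.raises(ic.ConfigurationError, match="strict subset"):
            ic.transfer_train(old_model, new_fm, y,
                              ic.TransferSpec(frozen_layers=(1, 2)))

    def test_transfer_beats_scratch_at_small_fractions(self, setup):
        """With informative new features and little data, warm-starting from
        the old model is at least as good as training from scratch."""
        old_model, _, new_fm, y = setup
        rng = np.random.default_rng(0)
        wins = []
        for seed in range(5):
            sub = rng.choice(len(y), 60, replace=False)
            test = np.setdiff1d(np.arange(len(y)), sub)
            mask = np.isin(np.arange(len(y)), sub)
            fm = matrix(new_fm.values, names=list(new_fm.feature_names),
                        train_mask=mask)
            tspec = ic.TransferSpec(frozen_layers=(2,), fine_tune_epochs=40,
                                    learning_rate=3e-3, seed=seed)
            transferred = ic.transfer_train(old_model, fm, y, tspec)
            spec = ic.ModelSpec(hidden_layers=(12, 8), max_epochs=40,
                                seed=seed, learning_rate=3e-3)
            scratch = ic.train(fm, y, spec)
            a_t = ic.auroc(ic.predict_proba(transferred, fm)[test], y[test]).value
            a_s = ic.auroc(ic.predict_proba(scratch, fm)[test], y[test]).value
            wins.append(a_t - a_s)
        assert np.mean(wins) >= 0.0
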