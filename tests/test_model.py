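"""Classifier estimator: normalization, augmentations, training contract."""

import numpy as np
import pytest

from ppgsepsis.model import (
    AugmentConfig,
    ModelConfig,
    ResNet1DClassifier,
    TrainConfig,
    augment_jitter,
    augment_random_window,
    normalize_segment,
    train_fold,
)


class TestNormalize:
    def test_min_max_mapping(self):
        np.testing.assert_allclose(normalize_segment([0, 5, 10]), [-1, 0, 1])

    def test_already_normalized_unchanged(self):
        x = np.array([-1.0, 0.25, 1.0])
        np.testing.assert_allclose(normalize_segment(x), x)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize_segment(np.full(10, 2.0))


class TestAugmentations:
    def test_jitter_zero_std_identity(self):
        x = normalize_segment(np.sin(np.arange(100) * 0.3))
        np.testing.assert_array_equal(augment_jitter(x, 0.0, np.random.default_rng(0)), x)

    def test_jitter_output_spans_exact_range(self):
        x = normalize_segment(np.sin(np.arange(500) * 0.1))
        out = augment_jitter(x, 0.2, np.random.default_rng(1))
        assert out.min() == pytest.approx(-1.0)
        assert out.max() == pytest.approx(1.0)

    def test_jitter_reproducible(self):
        x = normalize_segment(np.sin(np.arange(100) * 0.3))
        a = augment_jitter(x, 0.1, np.random.default_rng(7))
        b = augment_jitter(x, 0.1, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_window_length(self):
        x = np.arange(15000.0)
        out = augment_random_window(x, 125, 90, np.random.default_rng(0))
        assert out.size == 11250

    def test_window_full_length_identity(self):
        x = np.arange(15000.0)
        out = augment_random_window(x, 125, 120, np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)

    def test_window_too_long_rejected(self):
        with pytest.raises(ValueError):
            augment_random_window(np.arange(100.0), 125, 90, np.random.default_rng(0))

    def test_window_starts_roughly_uniform(self):
        # chi-square sanity over 10 bins of the start position
        x = np.arange(15000.0)
        rng = np.random.default_rng(123)
        starts = [int(augment_random_window(x, 125, 90, rng)[0]) for _ in range(2000)]
        counts, _ = np.histogram(starts, bins=10, range=(0, 3750))
        expected = 2000 / 10
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        # 9 dof; 33.7 is far beyond the 0.9999 quantile
        assert chi2 < 33.7


def _toy_dataset(n_per_class=12, length=256, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(size=(n_per_class, length))
    x1 = rng.normal(size=(n_per_class, length)) + 2.0
    X = np.vstack([x0, x1])
    X = np.array([normalize_segment(r) for r in X])
    # separable through the normalized shape? add a frequency cue instead
    t = np.arange(length)
    X[n_per_class:] += 0.4 * np.sin(2 * np.pi * t / 16)
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    return X, y


def _small_clf(**kw):
    defaults = dict(n_identity_blocks=2, n_filters=4, dense_units=8,
                    input_length=256, learning_rate=1e-3, batch_size=8,
                    epochs=2, random_state=0)
    defaults.update(kw)
    return ResNet1DClassifier(**defaults)


class TestClassifier:
    def test_history_and_best_val_loss_contract(self):
        X, y = _toy_dataset()
        clf = _small_clf(epochs=2).fit(X, y, X_val=X, y_val=y)
        assert len(clf.history_) == 2
        assert clf.best_val_loss_ == pytest.approx(min(v for _, v in clf.history_))

    def test_deterministic_given_seed(self):
        X, y = _toy_dataset()
        a = _small_clf(epochs=2).fit(X, y, X_val=X, y_val=y)
        b = _small_clf(epochs=2).fit(X, y, X_val=X, y_val=y)
        assert a.best_val_loss_ == b.best_val_loss_
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_subject_overlap_rejected(self):
        X, y = _toy_dataset()
        with pytest.raises(ValueError, match="overlap"):
            _small_clf().fit(X, y, X_val=X[:4], y_val=y[:4],
                             groups=["a"] * len(y), val_groups=["a"] * 4)

    def test_empty_sets_rejected(self):
        X, y = _toy_dataset()
        with pytest.raises(ValueError):
            _small_clf().fit(X[:0], y[:0])
        with pytest.raises(ValueError):
            _small_clf().fit(X, y, X_val=X[:0], y_val=y[:0])

    def test_wrong_input_length_rejected(self):
        X, y = _toy_dataset()
        clf = _small_clf().fit(X, y)
        with pytest.raises(ValueError):
            clf.predict_proba(X[:, :100])

    def test_predict_proba_batch_order_independent(self):
        X, y = _toy_dataset()
        clf = _small_clf().fit(X, y)
        p = clf.predict_proba(X)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(clf.predict_proba(X[perm]), p[perm], atol=1e-6)

    def test_learning_reduces_validation_loss(self):
        # separable classes: validation loss should halve within 30 epochs
        X, y = _toy_dataset(n_per_class=24)
        Xv, yv = _toy_dataset(n_per_class=8, seed=5)
        clf = _small_clf(epochs=30, learning_rate=1e-3).fit(X, y, X_val=Xv, y_val=yv)
        first_val = clf.history_[0][1]
        assert clf.best_val_loss_ <= 0.5 * first_val

    def test_sklearn_get_set_params_roundtrip(self):
        clf = _small_clf()
        params = clf.get_params()
        clone = ResNet1DClassifier(**params)
        assert clone.get_params() == params

    def test_save_load_round_trip(self, tmp_path):
        X, y = _toy_dataset()
        clf = _small_clf(epochs=2).fit(X, y, X_val=X, y_val=y)
        clf.save(tmp_path / "model.npz")
        back = type(clf).load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.classes_, clf.classes_)
        np.testing.assert_allclose(back.predict_proba(X), clf.predict_proba(X),
                                   atol=1e-6)
        assert back.best_val_loss_ == pytest.approx(clf.best_val_loss_)

    def test_random_window_training_crops_inference_inputs(self):
        X, y = _toy_dataset(n_per_class=8, length=256)
        clf = _small_clf(window_enabled=True, window_s=1.0, fs=128.0,
                         input_length=256, epochs=1).fit(X, y)
        # network built at 128 samples; full-length inputs are center-cropped
        assert clf.net_.cfg["input_length"] == 128
        p = clf.predict_proba(X)
        assert p.shape == (len(X), 2)


class TestTrainFold:
    def test_contract_and_disjointness_check(self):
        X, y = _toy_dataset()
        mc = ModelConfig(n_identity_blocks=2, n_filters=4, dense_units=8,
                         input_length=256)
        tc = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=2, seed=0)
        tf = train_fold((X, y), (X, y), mc, tc, AugmentConfig(), fold_id=3,
                        train_subjects=["a"] * len(y), val_subjects=["b"] * len(y))
        assert tf.fold_id == 3
        assert len(tf.history) == 2
        assert tf.best_val_loss == pytest.approx(min(v for _, v in tf.history))
        with pytest.raises(ValueError):
            train_fold((X, y), (X, y), mc, tc, AugmentConfig(),
                       train_subjects=["a"], val_subjects=["a"])

    def test_null_classes_keep_chance_level_loss(self):
        # indistinguishable classes: validation loss stays near ln 2
        rng = np.random.default_rng(0)
        X = rng.normal(size=(48, 256))
        y = np.r_[np.zeros(24, int), np.ones(24, int)]
        mc = ModelConfig(n_identity_blocks=2, n_filters=4, dense_units=8,
                         input_length=256)
        tc = TrainConfig(learning_rate=1e-4, batch_size=8, epochs=20, seed=1)
        tf = train_fold((X, y), (rng.normal(size=(24, 256)),
                                 np.r_[np.zeros(12, int), np.ones(12, int)]),
                        mc, tc)
        final_val = tf.history[-1][1]
        assert abs(final_val - np.log(2)) < 0.1
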