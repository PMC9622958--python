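"""Majority voting, confusion metrics, ROC/AUC, ensemble evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgsepsis.evaluate import (
    ConfusionCounts,
    MajorityVoteEnsemble,
    UndefinedMetricError,
    confusion,
    ensemble_score,
    evaluate_ensemble,
    majority_vote,
    metrics,
    roc_auc,
    subject_level_report,
)


class TestMajorityVote:
    def test_examples(self):
        assert majority_vote([1, 1, 0, 1, 0]) == 1
        assert majority_vote([0, 0, 0, 0, 0]) == 0

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([1, 0])

    def test_exhaustive_against_count_oracle(self):
        for votes in itertools.product((0, 1), repeat=5):
            expected = 1 if sum(votes) >= 3 else 0  # brute-force count
            assert majority_vote(votes) == expected


class TestEnsembleScore:
    def test_mean(self):
        assert ensemble_score([0.2, 0.4, 0.6, 0.8, 1.0]) == pytest.approx(0.6)

    def test_all_equal(self):
        assert ensemble_score([0.3] * 5) == pytest.approx(0.3)

    def test_mean_and_vote_can_diverge(self):
        probs = [0.9, 0.9, 0.4, 0.4, 0.4]
        assert ensemble_score(probs) == pytest.approx(0.6)
        assert majority_vote([int(p >= 0.5) for p in probs]) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ensemble_score([0.5, 1.2])


class TestConfusionMetrics:
    def test_counts_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_and_all_wrong(self):
        assert confusion([1, 0], [1, 0]).fn == 0
        c = confusion([1, 0], [0, 1])
        assert c.tp == 0 and c.tn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_metric_values(self):
        m = metrics(ConfusionCounts(tp=70, fn=30, tn=81, fp=19))
        assert m["accuracy"] == pytest.approx(0.755)
        assert m["sensitivity"] == pytest.approx(0.70)
        assert m["specificity"] == pytest.approx(0.81)

    def test_balanced_half(self):
        m = metrics(ConfusionCounts(tp=1, fn=1, tn=1, fp=1))
        assert m == {"accuracy": 0.5, "sensitivity": 0.5, "specificity": 0.5}

    def test_empty_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))

    @given(tp=st.integers(0, 200), fn=st.integers(0, 200),
           tn=st.integers(0, 200), fp=st.integers(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_accuracy_identity(self, tp, fn, tn, fp):
        # accuracy = (sens*P + spec*N) / (P+N) exactly
        if tp + fn == 0 or tn + fp == 0:
            return
        m = metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
        P, N = tp + fn, tn + fp
        assert m["accuracy"] == pytest.approx(
            (m["sensitivity"] * P + m["specificity"] * N) / (P + N), abs=1e-12)


def _mann_whitney_auc(scores, y):
    """O(n^2) pairwise-concordance oracle (ties count half)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_identical_scores_chance(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        # quantized scores to exercise tie handling
        scores = np.round(rng.uniform(0, 1, n), 2)
        _, auc = roc_auc(scores, y)
        assert auc == pytest.approx(_mann_whitney_auc(scores, y), abs=1e-12)

    def test_roc_is_monotone_staircase(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        roc, _ = roc_auc(rng.uniform(0, 1, 40), y)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)
        np.testing.assert_allclose(roc[0], [0, 0])
        np.testing.assert_allclose(roc[-1], [1, 1])

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.uniform(0.01, 0.99, 60)
        _, a1 = roc_auc(s, y)
        _, a2 = roc_auc(np.log(s / (1 - s)), y)  # strictly monotone
        assert a1 == pytest.approx(a2, abs=1e-12)


class _FakeModel:
    """Duck-typed stand-in classifier with fixed per-sample scores."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        s = self.scores[: len(X)]
        return np.column_stack([1 - s, s])


class TestEvaluateEnsemble:
    def _setup(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        X = np.zeros((6, 4))
        good = _FakeModel([0.9, 0.8, 0.7, 0.2, 0.1, 0.3])
        models = [good] * 5
        return X, y, models

    def test_identical_folds_match_single_fold_metrics(self):
        X, y, models = self._setup()
        res = evaluate_ensemble(models, X, y)
        assert res.ensemble_metrics == res.per_model_metrics[0]
        assert res.auc == pytest.approx(1.0)

    def test_report_has_k_plus_one_rows(self):
        X, y, models = self._setup()
        res = evaluate_ensemble(models, X, y)
        report = res.report()
        assert len(report) == 6
        assert report["model"].tolist()[-1] == "Ensemble"

    def test_vote_is_majority_of_columns(self):
        X = np.zeros((4, 2))
        y = np.array([1, 0, 1, 0])
        models = [_FakeModel([0.9, 0.1, 0.2, 0.2]),
                  _FakeModel([0.8, 0.6, 0.3, 0.1]),
                  _FakeModel([0.7, 0.2, 0.9, 0.4]),
                  _FakeModel([0.1, 0.3, 0.2, 0.6]),
                  _FakeModel([0.9, 0.1, 0.1, 0.2])]
        res = evaluate_ensemble(models, X, y)
        np.testing.assert_array_equal(res.vote, [1, 0, 0, 0])
        np.testing.assert_allclose(res.score, np.mean(
            [m.scores for m in models], axis=0))

    def test_subject_overlap_rejected(self):
        X, y, models = self._setup()
        with pytest.raises(ValueError, match="seen in training"):
            evaluate_ensemble(models, X, y,
                              test_subjects=["a", "a", "b", "b", "c", "c"],
                              train_subjects={"b"})

    def test_majority_vote_estimator_wrapper(self):
        X = np.zeros((4, 2))
        models = [_FakeModel([0.9, 0.1, 0.2, 0.2]),
                  _FakeModel([0.8, 0.6, 0.3, 0.1]),
                  _FakeModel([0.7, 0.2, 0.9, 0.4]),
                  _FakeModel([0.1, 0.3, 0.2, 0.6]),
                  _FakeModel([0.9, 0.1, 0.1, 0.2])]
        ens = MajorityVoteEnsemble(models).fit()
        np.testing.assert_array_equal(ens.predict(X), [1, 0, 0, 0])
        np.testing.assert_allclose(ens.predict_proba(X)[:, 1],
                                   np.mean([m.scores for m in models], axis=0))
        with pytest.raises(ValueError):
            MajorityVoteEnsemble(models[:4]).fit()

    def test_subject_level_report(self):
        X, y, models = self._setup()
        res = evaluate_ensemble(models, X, y)
        rep = subject_level_report(res, y, ["p1", "p1", "p1", "p2", "p2", "p2"])
        assert rep.loc[rep.subject == "p1", "pred"].item() == 1
        assert rep.loc[rep.subject == "p2", "pred"].item() == 0
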