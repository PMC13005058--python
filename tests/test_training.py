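"""Fold construction, scaling, the training loop, and metric formulas."""

from __future__ import annotations

import numpy as np
import pytest

from turnsignal import (
    ModelSpec, SeriesTensor, TrainConfig, class_weights, cross_validate,
    evaluate, fit_scaler, make_folds, train_model,
)
from turnsignal.training import (
    MetricsReport, _mean_reports, cosine_lr, metrics_from_probabilities,
)


class TestFolds:
    def test_21_participants_7_folds_of_3(self):
        pids = [f"p{i}" for i in range(21)]
        labels = {p: ("mci" if i < 7 else "healthy") for i, p in enumerate(pids)}
        folds = make_folds(pids, labels, k=7, seed=0)
        assert len(folds) == 7
        for _, test in folds:
            assert len(test) == 3

    def test_stratified_round_robin_ratio(self):
        pids = [f"a{i}" for i in range(14)] + [f"b{i}" for i in range(7)]
        labels = {p: ("healthy" if p[0] == "a" else "mci") for p in pids}
        for train, test in make_folds(pids, labels, k=7, seed=3):
            assert sum(p[0] == "a" for p in test) == 2
            assert sum(p[0] == "b" for p in test) == 1

    def test_no_leakage_and_full_coverage(self):
        pids = [f"p{i}" for i in range(19)]
        labels = {p: ("mci" if i % 3 == 0 else "healthy") for i, p in enumerate(pids)}
        folds = make_folds(pids, labels, k=7, seed=1)
        covered = set()
        for train, test in folds:
            assert train & test == set()
            assert train | test == set(pids)
            assert not (covered & test)
            covered |= test
        assert covered == set(pids)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c", "d", "e", "f", "g"], ["healthy"] * 7, k=7)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], {"a": "mci", "b": "healthy"}, k=7)


class TestClassWeights:
    def test_balanced_identity(self):
        np.testing.assert_allclose(class_weights(np.repeat([0, 1], 25)), [1.0, 1.0])

    def test_imbalanced_formula(self):
        w = class_weights(np.array([0] * 30 + [1] * 10))
        np.testing.assert_allclose(w, [40 / 60, 40 / 20])

    def test_permutation_invariance(self, rng):
        y = np.array([0] * 12 + [1] * 5)
        np.testing.assert_allclose(class_weights(y), class_weights(rng.permutation(y)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.ones(5))


class TestScaler:
    def test_train_tensor_standardized(self, rng):
        x = rng.standard_normal((20, 4, 50)) * 3 + 7
        sc = fit_scaler(x)
        z = sc.transform(x)
        np.testing.assert_allclose(z.mean(axis=(0, 2)), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=(0, 2)), 1.0, atol=1e-9)

    def test_constant_channel_guarded(self, rng):
        x = rng.standard_normal((10, 2, 30))
        x[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            sc = fit_scaler(x)
        z = sc.transform(x)
        np.testing.assert_allclose(z[:, 1], 0.0)

    def test_test_set_uses_train_statistics(self, rng):
        train = rng.standard_normal((20, 3, 40))
        test = train + 2.0  # shifted distribution
        sc = fit_scaler(train)
        z = sc.transform(test)
        own = fit_scaler(test).transform(test)
        assert not np.allclose(z, own)
        np.testing.assert_allclose(z.mean(axis=(0, 2)), 2.0 / sc.std, atol=1e-9)


class TestTrainingLoop:
    def test_separable_toy_reaches_full_accuracy(self, rng):
        y = np.repeat([0, 1], 32)
        x = rng.standard_normal((64, 10, 30)) + y[:, None, None] * 2.0
        spec = ModelSpec("cnn1d", in_channels=10)
        model, hist = train_model(spec, x, y, TrainConfig(epochs=40, seed=0))
        from turnsignal import predict_proba

        pred = (predict_proba(model, x)[:, 1] >= 0.5).astype(int)
        assert (pred == y).mean() == 1.0

    def test_history_length_matches_epochs(self, rng):
        y = np.array([0, 1] * 8)
        x = rng.standard_normal((16, 10, 20))
        _, hist = train_model(ModelSpec("cnn1d"), x, y, TrainConfig(epochs=1, seed=0))
        assert len(hist) == 1

    def test_same_seed_identical_history(self, rng):
        y = np.array([0, 1] * 8)
        x = rng.standard_normal((16, 10, 20))
        cfg = TrainConfig(epochs=5, seed=7)
        _, h1 = train_model(ModelSpec("cnn1d"), x, y, cfg)
        _, h2 = train_model(ModelSpec("cnn1d"), x, y, cfg)
        assert h1 == h2

    def test_cosine_schedule_endpoints(self):
        assert cosine_lr(1e-3, 0, 200) == pytest.approx(1e-3)
        assert cosine_lr(1e-3, 200, 200) == pytest.approx(0.0, abs=1e-12)
        assert cosine_lr(1e-3, 100, 200) == pytest.approx(5e-4)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = metrics_from_probabilities(y, np.array([0.1, 0.9, 0.2, 0.8]))
        for name in ("accuracy", "balanced_accuracy", "auc", "precision", "recall", "f1"):
            assert rep.as_dict()[name] == 1.0

    def test_uninformative_constant_probability(self):
        y = np.array([0, 1] * 10)
        rep = metrics_from_probabilities(y, np.full(20, 0.5))
        assert rep.auc == pytest.approx(0.5)

    def test_hand_computed_confusion_table(self):
        """TP=2 FN=1 TN=10 FP=3 reproduces the textbook formula values."""
        y = np.array([1, 1, 1] + [0] * 13)
        p = np.array([0.9, 0.8, 0.1] + [0.7] * 3 + [0.2] * 10)
        rep = metrics_from_probabilities(y, p)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (2, 1, 10, 3)
        assert rep.accuracy == pytest.approx(12 / 16)
        assert rep.precision == pytest.approx(0.4)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.balanced_accuracy == pytest.approx((2 / 3 + 10 / 13) / 2)
        assert rep.f1 == pytest.approx(2 * 0.4 * (2 / 3) / (0.4 + 2 / 3))

    def test_balanced_classes_accuracy_equals_balanced_accuracy(self, rng):
        y = np.repeat([0, 1], 20)
        p = rng.random(40)
        rep = metrics_from_probabilities(y, p)
        assert abs(rep.accuracy - rep.balanced_accuracy) < 1e-9

    def test_single_class_auc_missing(self):
        rep = metrics_from_probabilities(np.zeros(5, int), np.random.rand(5))
        assert rep.auc is None

    def test_fold_mean_arithmetic(self):
        a = MetricsReport(0.6, 0.6, 0.6, 0.6, 0.6, 0.6)
        b = MetricsReport(0.8, 0.8, 0.8, 0.8, 0.8, 0.8)
        mean = _mean_reports([a, b])
        assert mean.accuracy == pytest.approx(0.7)
        assert mean.auc == pytest.approx(0.7)

    def test_fold_mean_skips_missing_auc(self):
        a = MetricsReport(0.6, 0.6, None, 0.6, 0.6, 0.6)
        b = MetricsReport(0.8, 0.8, 0.9, 0.8, 0.8, 0.8)
        assert _mean_reports([a, b]).auc == pytest.approx(0.9)

    def test_evaluate_empty_test_rejected(self, rng):
        from turnsignal import build_model

        m = build_model(ModelSpec("cnn1d"))
        with pytest.raises(ValueError):
            evaluate(m, np.zeros((0, 10, 20)), np.zeros(0))


class TestCrossValidate:
    def _toy_tensor(self, rng, n_per=4, n_pid=8, L=24, effect=2.0):
        pids, labels, rows = [], [], []
        for i in range(n_pid):
            mci = i % 2 == 1
            for k in range(n_per):
                rows.append(rng.standard_normal((10, L)) + (effect if mci else 0.0))
                pids.append(f"p{i}")
                labels.append(int(mci))
        return SeriesTensor(np.stack(rows), np.array(labels),
                            np.array(pids, object),
                            np.array([str(k) for k in range(len(rows))], object),
                            "trip")

    def test_leakage_guard_and_recovery(self, rng):
        t = self._toy_tensor(rng)
        folds = make_folds(sorted(set(t.participant_ids)),
                           {p: ("mci" if int(p[1:]) % 2 else "healthy")
                            for p in t.participant_ids}, k=4, seed=0)
        mean, per_fold = cross_validate(
            ModelSpec("cnn1d"), t, TrainConfig(epochs=25, seed=0), folds)
        assert len(per_fold) == 4
        for r in per_fold:
            assert not (set(r.participant_ids) - r.test_participants)
        assert mean.auc > 0.9  # strong mean shift is trivially recoverable
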