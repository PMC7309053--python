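import numpy as np
import pytest

from ecgid import (
    ConfigurationError,
    SegmentSet,
    TrainConfig,
    build_architecture,
    evaluate,
    report_from_predictions,
    split_dataset,
    train,
)
from ecgid.training import loss_and_grads


def make_segments(windows_per_class, n_classes=3, length=30, seed=0):
    rng = np.random.default_rng(seed)
    windows, labels = [], []
    for c in range(n_classes):
        for _ in range(windows_per_class):
            windows.append(rng.normal(loc=c, size=length))
            labels.append(f"S{c}")
    return SegmentSet(np.stack(windows), labels, 360.0, "fixed_window")


class TestSplitDataset:
    def test_eighty_twenty_arithmetic(self):
        segs = make_segments(10)
        cfg = TrainConfig(seed=1)
        train_set, test_set = split_dataset(segs, cfg)
        assert len(train_set) == 24 and len(test_set) == 6
        for cls in ("S0", "S1", "S2"):
            assert train_set.labels.count(cls) == 8
            assert test_set.labels.count(cls) == 2

    def test_same_seed_same_split(self):
        segs = make_segments(7)
        a = split_dataset(segs, TrainConfig(seed=5))
        b = split_dataset(segs, TrainConfig(seed=5))
        assert np.array_equal(a[0].windows, b[0].windows)
        assert a[1].labels == b[1].labels

    def test_train_test_disjoint(self):
        segs = make_segments(9, seed=3)
        train_set, test_set = split_dataset(segs, TrainConfig(seed=2))
        train_rows = {tuple(w) for w in train_set.windows}
        test_rows = {tuple(w) for w in test_set.windows}
        assert not train_rows & test_rows

    @pytest.mark.parametrize("n_c", range(2, 21))
    def test_every_class_in_both_halves(self, n_c):
        segs = make_segments(n_c, n_classes=2)
        train_set, test_set = split_dataset(segs, TrainConfig(seed=0))
        for cls in ("S0", "S1"):
            assert train_set.labels.count(cls) >= 1
            assert test_set.labels.count(cls) >= 1

    def test_singleton_class_rejected_by_name(self):
        segs = make_segments(2)
        segs.windows = segs.windows[:-1]
        segs.labels = segs.labels[:-1]  # S2 now has one window
        with pytest.raises(ConfigurationError, match="S2"):
            split_dataset(segs, TrainConfig())

    def test_temporal_split_keeps_order(self):
        segs = make_segments(10, n_classes=1)
        cfg = TrainConfig(seed=0, split_mode="temporal")
        train_set, test_set = split_dataset(segs, cfg)
        assert np.array_equal(train_set.windows, segs.windows[:8])
        assert np.array_equal(test_set.windows, segs.windows[8:])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central finite differences on a
        tiny bidirectional model (the whole training path in miniature)."""
        model = build_architecture(5, num_classes=2, hidden_dim=3, seed=4)
        rng = np.random.default_rng(0)
        model.output_weight += rng.normal(scale=0.5, size=model.output_weight.shape)
        X = rng.normal(size=(2, 5, 1))
        y = np.array([0, 1])
        _, grads = loss_and_grads(model, X, y)
        eps = 1e-6
        for p, g in zip(model.parameters(), grads):
            flat = p.reshape(-1)
            for j in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = loss_and_grads(model, X, y)
                flat[j] = orig - eps
                lm, _ = loss_and_grads(model, X, y)
                flat[j] = orig
                numeric = (lp - lm) / (2 * eps)
                assert np.isclose(g.reshape(-1)[j], numeric, atol=1e-6), (
                    p.shape,
                    j,
                )

    def test_last_step_fusion_gradients(self):
        model = build_architecture(2, num_classes=2, hidden_dim=2, seed=1)
        rng = np.random.default_rng(3)
        model.output_weight += rng.normal(scale=0.5, size=model.output_weight.shape)
        X = rng.normal(size=(3, 4, 1))
        y = np.array([0, 1, 0])
        _, grads = loss_and_grads(model, X, y)
        eps = 1e-6
        p = model.parameters()[0]
        orig = p[0, 0]
        p[0, 0] = orig + eps
        lp, _ = loss_and_grads(model, X, y)
        p[0, 0] = orig - eps
        lm, _ = loss_and_grads(model, X, y)
        p[0, 0] = orig
        assert np.isclose(grads[0][0, 0], (lp - lm) / (2 * eps), atol=1e-6)


class TestTrain:
    def test_initial_loss_is_log_c_for_uniform_scores(self):
        # a zeroed score head makes the initial softmax uniform, so the
        # starting cross-entropy on balanced classes is exactly ln(C)
        segs = make_segments(6, n_classes=4, seed=1)
        model = build_architecture(4, num_classes=4, hidden_dim=4, seed=0)
        model.output_weight[:] = 0.0
        _, trace = train(model, segs, TrainConfig(epochs=1, batch_size=24, seed=0))
        assert abs(trace[0] - np.log(4)) < 1e-5  # single-precision epoch loss

    def test_separable_two_class_fixture_reaches_perfect_accuracy(self):
        # disjoint amplitude regimes: trivially separable
        segs = make_segments(10, n_classes=2, length=20, seed=2)
        model = build_architecture(4, num_classes=2, hidden_dim=8, seed=0)
        cfg = TrainConfig(epochs=25, batch_size=8, seed=0)
        model, trace = train(model, segs, cfg)
        report = evaluate(model, segs)
        assert report.overall_accuracy == 1.0
        assert trace[-1] <= trace[0]

    def test_same_seed_identical_loss_trace(self):
        segs = make_segments(5, n_classes=2, seed=4)
        cfgs = [TrainConfig(epochs=3, batch_size=5, seed=9) for _ in range(2)]
        traces = []
        for cfg in cfgs:
            model = build_architecture(4, num_classes=2, hidden_dim=4, seed=9)
            _, trace = train(model, segs, cfg)
            traces.append(trace)
        assert traces[0] == traces[1]

    def test_unknown_label_rejected(self):
        segs = make_segments(4, n_classes=2)
        model = build_architecture(4, num_classes=2, hidden_dim=3, seed=0)
        model.class_names = ["A", "B"]
        with pytest.raises(ConfigurationError):
            train(model, segs, TrainConfig(epochs=1))


class TestEvaluate:
    def test_perfect_predictions_give_all_ones(self):
        y = np.array([0, 1, 2, 0, 1, 2, 2])
        report = report_from_predictions(y, y, 3)
        assert report.overall_accuracy == 1.0
        assert report.overall_precision == 1.0
        assert report.overall_recall == 1.0
        assert report.f1_score == 1.0

    def test_hand_worked_three_class_counts(self):
        # per-class tp=(8,9,7), fp=(2,1,3), fn=(2,1,3), N=30
        y_true = [0] * 10 + [1] * 10 + [2] * 10
        y_pred = (
            [0] * 8 + [2] * 2          # true 0: 8 correct, 2 stray to class 2
            + [1] * 9 + [2] * 1        # true 1: 9 correct, 1 stray to class 2
            + [2] * 7 + [0] * 2 + [1] * 1  # true 2: 7 correct
        )
        report = report_from_predictions(np.array(y_true), np.array(y_pred), 3)
        conf = report.confusion
        assert conf.tp.tolist() == [8, 9, 7]
        assert conf.fp.tolist() == [2, 1, 3]
        assert conf.fn.tolist() == [2, 1, 3]
        assert np.isclose(report.overall_accuracy, 24 / 30)
        assert np.isclose(report.overall_precision, np.mean([8 / 10, 9 / 10, 7 / 10]))

    def test_single_class_f1_reduces_to_harmonic_mean(self):
        y_true = np.zeros(10, dtype=int)
        y_pred = np.zeros(10, dtype=int)
        report = report_from_predictions(y_true, y_pred, 1)
        assert report.f1_score == 1.0

    def test_zero_predicted_positives_contribute_zero(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 0, 0])
        with pytest.warns(UserWarning):
            report = report_from_predictions(y_true, y_pred, 2)
        assert report.per_class_precision[1] == 0.0
        assert np.isfinite(report.f1_score)

    def test_matches_sklearn_on_random_vectors(self):
        """Independent oracle: sklearn's metrics on 1000 random instances."""
        from sklearn.metrics import (
            accuracy_score,
            confusion_matrix,
            f1_score,
            precision_score,
            recall_score,
        )
        import warnings

        rng = np.random.default_rng(99)
        for _ in range(1000):
            C = int(rng.integers(2, 6))
            N = int(rng.integers(2, 51))
            y_true = rng.integers(0, C, N)
            y_pred = rng.integers(0, C, N)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = report_from_predictions(y_true, y_pred, C)
                labels = np.arange(C)
                assert np.array_equal(
                    report.confusion.matrix, confusion_matrix(y_true, y_pred, labels=labels)
                )
                assert np.isclose(report.overall_accuracy, accuracy_score(y_true, y_pred))
                assert np.isclose(
                    report.overall_precision,
                    precision_score(y_true, y_pred, labels=labels, average="macro", zero_division=0),
                )
                assert np.isclose(
                    report.overall_recall,
                    recall_score(y_true, y_pred, labels=labels, average="macro", zero_division=0),
                )
                assert np.isclose(
                    report.f1_score,
                    f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0),
                )

    def test_accuracy_equals_direct_fraction_correct(self):
        rng = np.random.default_rng(5)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = report_from_predictions(y_true, y_pred, 4)
        assert np.isclose(report.overall_accuracy, np.mean(y_true == y_pred))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        perm = np.array([2, 0, 1])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = report_from_predictions(y_true, y_pred, 3)
            b = report_from_predictions(perm[y_true], perm[y_pred], 3)
        assert np.isclose(a.overall_accuracy, b.overall_accuracy)
        assert np.isclose(a.overall_precision, b.overall_precision)
        assert np.isclose(a.overall_recall, b.overall_recall)
        assert np.isclose(a.f1_score, b.f1_score)
        # per-class values permute along with the labels
        inv = np.argsort(perm)
        assert np.allclose(a.per_class_precision, b.per_class_precision[perm])

    def test_metrics_always_in_unit_interval(self):
        rng = np.random.default_rng(13)
        import warnings

        for _ in range(100):
            C = int(rng.integers(2, 5))
            N = int(rng.integers(2, 30))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = report_from_predictions(
                    rng.integers(0, C, N), rng.integers(0, C, N), C
                )
            for v in (r.overall_accuracy, r.overall_precision, r.overall_recall, r.f1_score):
                assert 0.0 <= v <= 1.0

    def test_empty_test_set_rejected(self):
        segs = SegmentSet(np.empty((0, 10)), [], 360.0, "fixed_window")
        model = build_architecture(1, num_classes=2, hidden_dim=2, seed=0)
        model.class_names = ["a", "b"]
        with pytest.raises(ConfigurationError):
            evaluate(model, segs)
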