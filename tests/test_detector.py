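"""The convolutional BS/non-BS classifier."""

import numpy as np
import pytest

from borborygmi._cnn import (
    Conv2D,
    Dense,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    cross_entropy_grad,
)
from borborygmi.detector import (
    BSDetector,
    DetectorConfig,
    EvalMetrics,
    train_val_split,
)
from borborygmi.features import MelDataset, PreprocessConfig


def make_dataset(n=64, seed=0, tone_vs_silence=False):
    """Random (or trivially separable) 128x3 datasets."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    if tone_vs_silence:
        X = np.zeros((n, 128, 3))
        for i in range(n):
            if y[i] == 1:
                band = rng.integers(20, 100)
                X[i, band - 2:band + 3, :] = 1.0
            else:
                X[i] = 0.05 * rng.random((128, 3))
    else:
        X = rng.random((n, 128, 3))
    sub = np.array([""] * n, dtype="U4")
    return MelDataset(X, y, sub, np.zeros(n), PreprocessConfig())


class TestBuildModel:
    def test_probabilities_sum_to_one(self):
        det = BSDetector(DetectorConfig(seed=1))
        X = np.random.default_rng(0).random((7, 128, 3))
        p = det.predict_proba(X)
        logits = det.net.forward(det._as_array(X))
        from borborygmi._cnn import softmax
        assert np.allclose(softmax(logits).sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_input_shape_is_exactly_128x3(self):
        det = BSDetector()
        with pytest.raises(ValueError):
            det.predict_proba(np.zeros((2, 129, 3)))
        with pytest.raises(ValueError):
            det.predict_proba(np.zeros((2, 128, 4)))

    def test_dropout_zero_same_architecture(self):
        a = BSDetector(DetectorConfig(dropout_rate=0.0, seed=0))
        b = BSDetector(DetectorConfig(dropout_rate=0.2, seed=0))
        assert a.n_params == b.n_params

    def test_pool_on_time_axis_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(pool=(2, 2))

    def test_parameter_count_reported(self):
        det = BSDetector()
        assert det.n_params > 0


class TestTraining:
    def test_history_has_one_entry_per_epoch(self):
        ds = make_dataset(96, tone_vs_silence=True)
        tr, va = train_val_split(ds, 0.3, 0)
        det = BSDetector(DetectorConfig(epochs=4, seed=0))
        hist = det.train(tr, va)
        assert len(hist["val_accuracy"]) == 4
        assert len(hist["train_accuracy"]) == 4

    def test_separable_data_learned_perfectly(self):
        ds = make_dataset(256, seed=1, tone_vs_silence=True)
        tr, va = train_val_split(ds, 0.3, 1)
        det = BSDetector(DetectorConfig(epochs=5, seed=1))
        det.train(tr, va)
        assert det.history["val_accuracy"][-1] == 1.0

    def test_single_class_rejected(self):
        ds = make_dataset(32)
        ds.y[:] = 1
        det = BSDetector(DetectorConfig(epochs=1))
        with pytest.raises(ValueError):
            det.train(ds, ds)

    def test_training_deterministic_given_seed(self):
        ds = make_dataset(96, tone_vs_silence=True)
        tr, va = train_val_split(ds, 0.3, 0)
        hists = []
        for _ in range(2):
            det = BSDetector(DetectorConfig(epochs=2, seed=7))
            hists.append(det.train(tr, va)["train_loss"])
        assert hists[0] == hists[1]


class TestInference:
    def test_empty_input(self):
        det = BSDetector()
        p = det.predict_proba(np.zeros((0, 128, 3)))
        assert p.size == 0

    def test_duplicated_sample_identical_probs(self):
        det = BSDetector(DetectorConfig(seed=2))
        x = np.random.default_rng(3).random((1, 128, 3))
        X = np.repeat(x, 10, axis=0)
        p = det.predict_proba(X)
        assert np.allclose(p, p[0])

    def test_batch_size_independent(self):
        det = BSDetector(DetectorConfig(seed=2))
        X = np.random.default_rng(4).random((33, 128, 3))
        a = det.predict_proba(X, batch_size=5)
        b = det.predict_proba(X, batch_size=512)
        assert np.allclose(a, b, atol=1e-6)

    def test_save_load_round_trip(self, tmp_path):
        ds = make_dataset(96, tone_vs_silence=True)
        tr, va = train_val_split(ds, 0.3, 0)
        det = BSDetector(DetectorConfig(epochs=2, seed=0))
        det.train(tr, va)
        det.save(tmp_path / "m")
        back = BSDetector.load(tmp_path / "m")
        X = np.random.default_rng(5).random((8, 128, 3))
        assert np.max(np.abs(det.predict_proba(X) - back.predict_proba(X))) < 1e-6
        assert back.cfg == det.cfg


class TestEvaluate:
    def _metrics(self, tp, fn, tn, fp):
        return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn)

    def test_confusion_arithmetic(self):
        m = self._metrics(tp=9, fn=1, tn=8, fp=2)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)
        assert m.accuracy == pytest.approx(0.85)

    def test_perfect_predictions(self):
        m = self._metrics(tp=10, fn=0, tn=10, fp=0)
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_undefined_metric_is_none_not_zero(self):
        m = self._metrics(tp=0, fn=0, tn=5, fp=1)
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(5 / 6)

    def test_balanced_accuracy_between_sens_and_spec(self):
        # with equal class sizes, accuracy is the mean of the two rates
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tp = int(rng.integers(0, 50)); fn = 50 - tp
            tn = int(rng.integers(0, 50)); fp = 50 - tn
            m = self._metrics(tp, fn, tn, fp)
            lo, hi = sorted([m.sensitivity, m.specificity])
            assert lo - 1e-12 <= m.accuracy <= hi + 1e-12

    def test_per_subtype_accuracy_proportion(self):
        ds = make_dataset(100, seed=6, tone_vs_silence=True)
        ds.subtype[ds.y == 1] = "SB"
        det = BSDetector(DetectorConfig(epochs=4, seed=3))
        tr, va = train_val_split(ds, 0.4, 0)
        det.train(tr, va)
        m = det.evaluate(va)
        _, yhat = det.predict(va)
        mask = (va.subtype == "SB") & (va.y == 1)
        assert m.per_subtype_accuracy["SB"] == pytest.approx(
            np.mean(yhat[mask] == 1))


class TestEngine:
    def test_gradients_match_finite_differences(self):
        # piecewise-linear kinks (ReLU, max pooling) make individual
        # finite differences occasionally jump an activation boundary, so
        # the check is distributional: nearly all sampled elements agree
        rng = np.random.default_rng(1)
        net = Sequential([Conv2D(2, 3, (3, 3), rng), ReLU(), MaxPool2D((2, 1)),
                          Flatten(), Dense(3 * 4 * 3, 2, rng)])
        x = rng.random((4, 8, 3, 2)).astype(np.float32)
        y = np.array([0, 1, 1, 0])
        logits = net.forward(x, train=True)
        _, g = cross_entropy_grad(logits, y)
        net.backward(g)
        eps = 1e-3
        rel_errs = []
        for p, dp in net.params():
            flat = p.reshape(-1)
            dflat = dp.reshape(-1)
            for k in range(0, flat.size, max(1, flat.size // 8)):
                flat[k] += eps
                l1, _ = cross_entropy_grad(net.forward(x), y)
                flat[k] -= 2 * eps
                l2, _ = cross_entropy_grad(net.forward(x), y)
                flat[k] += eps
                num = (l1 - l2) / (2 * eps)
                if abs(num) > 1e-4:
                    rel_errs.append(abs(dflat[k] - num) / abs(num))
        rel_errs = np.sort(rel_errs)
        assert rel_errs.size >= 20
        assert np.median(rel_errs) < 0.02
        assert np.mean(np.asarray(rel_errs) < 0.05) >= 0.9

    def test_pool_must_divide_input(self):
        with pytest.raises(ValueError):
            MaxPool2D((3, 1)).forward(np.zeros((1, 8, 3, 1)))
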