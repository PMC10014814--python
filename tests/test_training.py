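"""Training harness: splits, early stopping, freezing, evaluation."""

import numpy as np
import pytest

from relbench.backends import (
    CapabilityError,
    ClassifierBackend,
    LogisticBackend,
    SmallCNN,
    make_backend,
)
from relbench.training import (
    EvalResult,
    SplitError,
    TrainConfig,
    evaluate,
    split_dataset,
    train_with_early_stopping,
)


class ScriptedBackend(ClassifierBackend):
    """Backend whose per-epoch validation error follows a fixed script.

    ``fit_batch`` is a no-op; predictions flip exactly enough labels to
    realize the scripted error for the current epoch.
    """

    name = "scripted"
    supports_restricted = True
    input_size = 8
    params: dict = {}
    readout_params = frozenset()

    def __init__(self, errors, y_val):
        self.errors = list(errors)
        self.y_val = np.asarray(y_val)
        self.epoch = 0
        self.mode = "unrestricted"

    def on_epoch_start(self, epoch):
        self.epoch = epoch

    def fit_batch(self, X, y, lr, momentum=0.0):
        return 0.0

    def predict(self, X):
        err = self.errors[min(self.epoch - 1, len(self.errors) - 1)]
        if len(X) != len(self.y_val):  # training-set call: report perfect
            return np.zeros(len(X), dtype=int)
        k = int(round(err * len(self.y_val)))
        pred = self.y_val.copy()
        pred[:k] = 1 - pred[:k]
        return pred

    def predict_scores(self, X):
        return self.predict(X).astype(float)


def _toy_val(n=100, seed=0, size=8):
    rng = np.random.default_rng(seed)
    X = rng.random((n, size, size, 3)).astype(np.float32)
    y = rng.integers(2, size=n)
    return X, y


def _run_scripted(errors, patience=6, max_epochs=20):
    Xv, yv = _toy_val()
    backend = ScriptedBackend(errors, yv)
    cfg = TrainConfig(
        batch_size=10, learning_rate=0.1, max_epochs=max_epochs, patience=patience,
        seed=0,
    )
    Xt, yt = _toy_val(20, seed=1)
    return train_with_early_stopping(backend, (Xt, yt), (Xv, yv), cfg)[1]


# ---------------------------------------------------------------------------
# early stopping semantics
# ---------------------------------------------------------------------------


def test_patience_fires_after_six_consecutive_increases():
    # epoch 1-2 improve, then 6 strictly increasing checks end at epoch 8
    errors = [0.5, 0.40, 0.41, 0.42, 0.43, 0.44, 0.45, 0.46, 0.30, 0.30]
    trace = _run_scripted(errors)
    assert trace.stop_reason == "patience"
    assert trace.stop_epoch == 8
    assert len(trace.val_errors) == 8


def test_consecutive_counter_resets_on_any_non_increase():
    # five increases, a dip, five more increases: no stop within 12 epochs
    errors = [0.3, 0.31, 0.32, 0.33, 0.34, 0.35, 0.30, 0.31, 0.32, 0.33, 0.34, 0.35]
    trace = _run_scripted(errors, max_epochs=12)
    assert trace.stop_reason == "max_epochs"
    assert trace.stop_epoch == 12


def test_plateau_is_not_an_increase():
    errors = [0.4] * 12
    trace = _run_scripted(errors, max_epochs=12)
    assert trace.stop_reason == "max_epochs"


def test_monotone_decrease_runs_to_epoch_budget():
    errors = [0.5 - 0.02 * i for i in range(10)]
    trace = _run_scripted(errors, max_epochs=10)
    assert trace.stop_reason == "max_epochs"
    assert trace.stop_epoch == 10


def test_patience_one_stops_at_first_increase():
    errors = [0.4, 0.45, 0.2, 0.2]
    trace = _run_scripted(errors, patience=1)
    assert trace.stop_reason == "patience"
    assert trace.stop_epoch == 2


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def test_split_80_20(sd_small):
    tr, val = split_dataset(sd_small, 0.2, seed=0)
    assert len(tr) == 48 and len(val) == 12
    assert {r.image_id for r in tr.records}.isdisjoint(
        {r.image_id for r in val.records}
    )
    assert len(tr) + len(val) == len(sd_small)
    # stratified: both classes at the same rate
    assert val.class_counts() == {"same": 6, "different": 6}


def test_split_90_10(sd_small):
    tr, val = split_dataset(sd_small, 0.1, seed=0)
    assert len(tr) == 54 and len(val) == 6


def test_split_tiny_class_fails():
    from relbench.datasets import build_same_different_train

    m = build_same_different_train(n_per_class=1, seed=1)
    with pytest.raises(SplitError):
        split_dataset(m, 0.5)


# ---------------------------------------------------------------------------
# restricted-mode freezing
# ---------------------------------------------------------------------------


def test_restricted_mode_freezes_non_readout_parameters():
    X, y = _toy_val(80, seed=3, size=40)
    net = SmallCNN(input_size=40, channels=(4, 6, 8), seed=5)
    before = net.frozen_checksum()
    cfg = TrainConfig(
        mode="restricted", batch_size=16, learning_rate=0.05, max_epochs=3, seed=0
    )
    net, _ = train_with_early_stopping(net, (X[:60], y[:60]), (X[60:], y[60:]), cfg)
    assert net.frozen_checksum() == before
    # and the readout did change
    assert not np.allclose(net.fc.W, SmallCNN(input_size=40, channels=(4, 6, 8), seed=5).fc.W)


def test_unrestricted_mode_updates_everything():
    X, y = _toy_val(80, seed=3, size=40)
    net = SmallCNN(input_size=40, channels=(4, 6, 8), seed=5)
    before = net.frozen_checksum()
    cfg = TrainConfig(batch_size=16, learning_rate=0.05, max_epochs=3, seed=0)
    net, _ = train_with_early_stopping(net, (X[:60], y[:60]), (X[60:], y[60:]), cfg)
    assert net.frozen_checksum() != before


def test_capability_error_for_unknown_backend():
    with pytest.raises(CapabilityError):
        make_backend("resnet50")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


class ConstantModel(ClassifierBackend):
    input_size = 8

    def __init__(self, score):
        self.score = score

    def predict_scores(self, X):
        return np.full(len(X), self.score)


def test_evaluate_perfect_predictor():
    X, y = _toy_val(50, seed=2)

    class Echo(ConstantModel):
        def __init__(self, y):
            self.y = y

        def predict_scores(self, X):
            return self.y.astype(float)

    res = evaluate(Echo(y), (X, y))
    assert res.accuracy == 1.0


def test_evaluate_degenerate_one_class_predictor():
    """All-positive predictor on a balanced set: 50% overall, 100%/0% per class."""
    n = 100
    X = np.zeros((n, 8, 8, 3), dtype=np.float32)
    y = np.array([1, 0] * (n // 2))
    res = evaluate(ConstantModel(1.0), (X, y), class_names=("fewer", "more"))
    assert res.accuracy == 0.5
    assert res.per_class == {"fewer": 0.0, "more": 1.0}
    assert res.confusion == [[0, 50], [0, 50]]
    assert sum(map(sum, res.confusion)) == res.n


def test_evaluate_random_predictor_within_binomial_band():
    rng = np.random.default_rng(12)
    n = 1000
    X = np.zeros((n, 8, 8, 3), dtype=np.float32)
    y = np.array([0, 1] * (n // 2))

    class RandomModel(ConstantModel):
        def predict_scores(self, X):
            return rng.random(len(X))

    res = evaluate(RandomModel(0), (X, y))
    from scipy import stats as sps

    lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.5) / n
    assert lo <= res.accuracy <= hi


def test_smallcnn_sanity_two_image_task():
    """Two fixed images + pixel noise: near-perfect within 5 epochs."""
    rng = np.random.default_rng(0)
    base = rng.random((2, 56, 56, 3)).astype(np.float32)
    idx = rng.integers(2, size=240)
    X = np.clip(
        base[idx] + rng.normal(0, 0.05, (240, 56, 56, 3)), 0, 1
    ).astype(np.float32)
    y = idx
    net = SmallCNN(seed=1)
    cfg = TrainConfig(
        batch_size=32, learning_rate=0.01, momentum=0.9, max_epochs=5, seed=0
    )
    net, _ = train_with_early_stopping(net, (X[:180], y[:180]), (X[180:], y[180:]), cfg)
    assert evaluate(net, (X[180:], y[180:])).accuracy >= 0.95


def test_linearly_separable_readout_reaches_perfect_accuracy():
    """A linear readout separates linearly separable toy images exactly."""
    rng = np.random.default_rng(4)
    n = 200
    y = rng.integers(2, size=n)
    X = np.zeros((n, 8, 8, 3), dtype=np.float32)
    X[y == 1, :4] = 1.0  # top half bright iff class 1
    X += rng.normal(0, 0.01, X.shape).astype(np.float32)
    X = np.clip(X, 0, 1)
    model = LogisticBackend(input_size=8, seed=0)
    cfg = TrainConfig(batch_size=20, learning_rate=1.0, max_epochs=10, seed=0)
    model, trace = train_with_early_stopping(
        model, (X[:150], y[:150]), (X[150:], y[150:]), cfg
    )
    assert evaluate(model, (X[150:], y[150:])).accuracy == 1.0


def test_training_is_deterministic():
    X, y = _toy_val(60, seed=6, size=40)
    results = []
    for _ in range(2):
        net = SmallCNN(input_size=40, channels=(4, 6, 8), seed=9)
        cfg = TrainConfig(batch_size=16, learning_rate=0.02, max_epochs=2, seed=3)
        net, trace = train_with_early_stopping(
            net, (X[:40], y[:40]), (X[40:], y[40:]), cfg
        )
        results.append((tuple(trace.val_errors), net.fc.W.copy()))
    assert results[0][0] == results[1][0]
    assert np.array_equal(results[0][1], results[1][1])
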