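"""Classifier backends for the transfer-learning harness.

The harness is model-agnostic: anything satisfying :class:`ClassifierBackend`
can be trained.  Two concrete backends ship with the package:

* :class:`SmallCNN` — a compact convolutional classifier (two conv blocks,
  one hidden fully connected layer, softmax readout) implemented in pure
  numpy with explicit backpropagation.  It trains from scratch at desk scale
  and supports both protocols: *restricted* (all non-readout parameters
  frozen, only the final readout weights learn) and *unrestricted* (all
  parameters learn).
* :class:`LogisticBackend` — a linear softmax readout on raw pixels; the
  minimal linearly separable baseline.

Images enter as float32 ``(N, H, W, 3)`` arrays in ``[0, 1]`` at the
backend's ``input_size``; internally they are centered to ``[-0.5, 0.5]``.
"""

from __future__ import annotations

import hashlib
from typing import Optional

import numpy as np

MODES = ("restricted", "unrestricted")


class CapabilityError(RuntimeError):
    """The backend cannot honor the requested training mode."""


class ClassifierBackend:
    """Contract for trainable binary image classifiers.

    Subclasses implement :meth:`fit_batch` and :meth:`predict_scores`; the
    rest of the interface has sensible defaults.
    """

    name: str = "backend"
    input_size: int = 227
    supports_restricted: bool = False
    deterministic: bool = True

    def set_mode(self, mode: str) -> None:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "restricted" and not self.supports_restricted:
            raise CapabilityError(
                f"backend {self.name!r} does not support restricted transfer"
            )
        self.mode = mode

    #: error rate of the last fitted batch, measured before the update;
    #: lets the trainer track training error without an extra forward pass
    last_batch_error: Optional[float] = None

    def fit_batch(self, X: np.ndarray, y: np.ndarray, lr: float,
                  momentum: float = 0.0) -> float:
        """One SGD step on a minibatch; returns the batch loss."""
        raise NotImplementedError

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability in [0, 1] for each image."""
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)

    def frozen_checksum(self) -> str:
        """Hash of all non-readout parameters (restricted-mode freeze audit)."""
        h = hashlib.sha256()
        for name in sorted(self.params):
            if name not in self.readout_params:
                h.update(name.encode())
                h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()

    def on_epoch_start(self, epoch: int) -> None:  # pragma: no cover - hook
        pass

    # subclasses expose these for the checksum machinery
    params: dict[str, np.ndarray] = {}
    readout_params: frozenset[str] = frozenset()


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _prep(X: np.ndarray) -> np.ndarray:
    """(N, H, W, C) in [0,1] -> centered (N, C, H, W) float32."""
    X = np.asarray(X, dtype=np.float32)
    return np.transpose(X - 0.5, (0, 3, 1, 2))


class LogisticBackend(ClassifierBackend):
    """Linear softmax readout on flattened pixels; everything is readout."""

    name = "logistic"
    supports_restricted = True  # the freeze set is empty

    def __init__(self, input_size: int = 56, n_classes: int = 2, seed: int = 0):
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        d = input_size * input_size * 3
        self.params = {
            "W": (rng.standard_normal((d, n_classes)) * 0.01).astype(np.float32),
            "b": np.zeros(n_classes, dtype=np.float32),
        }
        self.readout_params = frozenset(self.params)
        self.mode = "unrestricted"
        self._vel = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _logits(self, X: np.ndarray) -> np.ndarray:
        flat = _prep(X).reshape(len(X), -1)
        return flat @ self.params["W"] + self.params["b"]

    def fit_batch(self, X, y, lr, momentum=0.0):
        flat = _prep(X).reshape(len(X), -1)
        logits = flat @ self.params["W"] + self.params["b"]
        p = _softmax(logits)
        n = len(X)
        onehot = np.zeros_like(p)
        onehot[np.arange(n), y] = 1.0
        dz = (p - onehot) / n
        self.last_batch_error = float((p.argmax(axis=1) != y).mean())
        grads = {"W": flat.T @ dz, "b": dz.sum(axis=0)}
        for k, g in grads.items():
            self._vel[k] = momentum * self._vel[k] - lr * g
            self.params[k] += self._vel[k]
        return float(-np.log(p[np.arange(n), y] + 1e-12).mean())

    def predict_scores(self, X):
        return _softmax(self._logits(X))[:, 1]


# ---------------------------------------------------------------------------
# the compact convolutional reference backend
# ---------------------------------------------------------------------------


def _conv_geometry(h: int, k: int, stride: int) -> int:
    return (h - k) // stride + 1


def _im2col(X: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, OH*OW, C*k*k) patches."""
    win = np.lib.stride_tricks.sliding_window_view(X, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, k, k)
    n, c, oh, ow, _, _ = win.shape
    return (
        win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k),
        oh,
        ow,
    )


class _ConvLayer:
    def __init__(self, c_in, c_out, k, stride, rng):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, fan_in))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.stride = k, stride

    def forward(self, X):
        cols, oh, ow = _im2col(X, self.k, self.stride)
        out = cols @ self.W.T + self.b  # (N, OH*OW, C_out)
        self.cache = (cols, X.shape, oh, ow)
        return out.transpose(0, 2, 1).reshape(len(X), -1, oh, ow)

    def backward(self, dout):
        cols, in_shape, oh, ow = self.cache
        n, c = dout.shape[0], in_shape[1]
        k, s = self.k, self.stride
        dflat = dout.reshape(n, -1, oh * ow).transpose(0, 2, 1)  # (N, OH*OW, C_out)
        self.dW = np.tensordot(dflat, cols, axes=([0, 1], [0, 1]))  # (C_out, Ck2)
        self.db = dflat.sum(axis=(0, 1))
        dcols = dflat @ self.W  # (N, OH*OW, C*k*k)
        # col2im as k*k strided adds (all-channel slices); much faster than scatter
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        dX = np.zeros(in_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dX[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        return dX


class _DenseLayer:
    def __init__(self, d_in, d_out, rng):
        self.W = (rng.standard_normal((d_in, d_out))
                  * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, X):
        self.cache = X
        return X @ self.W + self.b

    def backward(self, dout):
        X = self.cache
        self.dW = X.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


def _maxpool2(X):
    n, c, h, w = X.shape
    h2, w2 = h // 2 * 2, w // 2 * 2
    Xc = X[:, :, :h2, :w2].reshape(n, c, h2 // 2, 2, w2 // 2, 2)
    out = Xc.max(axis=(3, 5))
    mask = Xc == out[:, :, :, None, :, None]
    return out, (mask, X.shape)


def _maxpool2_backward(dout, cache):
    mask, in_shape = cache
    n, c, h, w = in_shape
    h2, w2 = h // 2 * 2, w // 2 * 2
    d = mask * dout[:, :, :, None, :, None]
    dX = np.zeros(in_shape, dtype=np.float32)
    dX[:, :, :h2, :w2] = d.reshape(n, c, h2, w2)
    return dX


_LEAK = 0.1  # leaky-ReLU slope; keeps small from-scratch nets trainable


def _lrelu(a):
    return np.where(a > 0, a, _LEAK * a)


def _dlrelu(a):
    return np.where(a > 0, 1.0, _LEAK).astype(np.float32)


class SmallCNN(ClassifierBackend):
    """Compact convolutional classifier trainable from scratch on one CPU.

    Architecture (default 56-px input): 5x5/2 conv -> leaky ReLU -> 2x2
    maxpool -> 3x3 conv -> leaky ReLU -> 2x2 maxpool -> 3x3 conv -> leaky
    ReLU -> global average pooling -> softmax readout.  The translation-
    invariant pooled head lets locally learned detectors vote wherever they
    fire, instead of memorizing position-specific activation patterns.

    The readout is the final dense layer on the pooled features; in
    restricted mode only the readout updates and every other parameter stays
    bit-identical.
    """

    name = "smallcnn"
    supports_restricted = True
    readout_params = frozenset({"fc.W", "fc.b"})

    def __init__(self, input_size: int = 56, channels=(12, 24, 32),
                 seed: int = 0, mode: str = "unrestricted",
                 clip_norm: float = 1.0):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.clip_norm = clip_norm
        self.conv1 = _ConvLayer(3, channels[0], k=5, stride=2, rng=rng)
        h = _conv_geometry(input_size, 5, 2) // 2  # after pool
        self.conv2 = _ConvLayer(channels[0], channels[1], k=3, stride=1, rng=rng)
        h = _conv_geometry(h, 3, 1) // 2
        self.conv3 = _ConvLayer(channels[1], channels[2], k=3, stride=1, rng=rng)
        h = _conv_geometry(h, 3, 1)
        if h < 1:
            raise ValueError(f"input_size {input_size} too small for this stack")
        self.fc = _DenseLayer(channels[2], 2, rng)
        self.set_mode(mode)
        self._vel: dict[str, np.ndarray] = {}

    # -- parameter bookkeeping ----------------------------------------------

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {
            "conv1.W": self.conv1.W, "conv1.b": self.conv1.b,
            "conv2.W": self.conv2.W, "conv2.b": self.conv2.b,
            "conv3.W": self.conv3.W, "conv3.b": self.conv3.b,
            "fc.W": self.fc.W, "fc.b": self.fc.b,
        }

    def _trainable(self) -> list[str]:
        if self.mode == "restricted":
            return sorted(self.readout_params)
        return sorted(self.params)

    # -- forward / backward ---------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool = False):
        a1 = self.conv1.forward(X)
        p1, cache1 = _maxpool2(_lrelu(a1))
        a2 = self.conv2.forward(p1)
        p2, cache2 = _maxpool2(_lrelu(a2))
        a3 = self.conv3.forward(p2)
        r3 = _lrelu(a3)
        pooled = r3.mean(axis=(2, 3))
        logits = self.fc.forward(pooled)
        if train:
            self._cache = (a1, cache1, a2, cache2, a3, r3.shape)
        return logits

    def fit_batch(self, X, y, lr, momentum=0.0):
        Xp = _prep(X)
        logits = self._forward(Xp, train=True)
        p = _softmax(logits)
        n = len(X)
        onehot = np.zeros_like(p)
        onehot[np.arange(n), y] = 1.0
        dz = ((p - onehot) / n).astype(np.float32)

        self.last_batch_error = float((p.argmax(axis=1) != y).mean())
        a1, cache1, a2, cache2, a3, r3_shape = self._cache
        dpooled = self.fc.backward(dz)
        n_pos = r3_shape[2] * r3_shape[3]
        dr3 = np.broadcast_to(dpooled[:, :, None, None], r3_shape) / n_pos
        da3 = dr3 * _dlrelu(a3)
        dp2 = self.conv3.backward(np.ascontiguousarray(da3, dtype=np.float32))
        dr2 = _maxpool2_backward(dp2, cache2)
        da2 = dr2 * _dlrelu(a2)
        dp1 = self.conv2.backward(np.ascontiguousarray(da2, dtype=np.float32))
        dr1 = _maxpool2_backward(dp1, cache1)
        da1 = dr1 * _dlrelu(a1)
        self.conv1.backward(np.ascontiguousarray(da1, dtype=np.float32))

        grads = {
            "conv1.W": self.conv1.dW, "conv1.b": self.conv1.db,
            "conv2.W": self.conv2.dW, "conv2.b": self.conv2.db,
            "conv3.W": self.conv3.dW, "conv3.b": self.conv3.db,
            "fc.W": self.fc.dW, "fc.b": self.fc.db,
        }
        # global-norm gradient clipping keeps long momentum-SGD runs from
        # diverging; a pure rescale, inactive for well-behaved batches
        gnorm = float(np.sqrt(sum(float((g**2).sum()) for g in grads.values())))
        if self.clip_norm and gnorm > self.clip_norm:
            grads = {k: g * (self.clip_norm / gnorm) for k, g in grads.items()}
        params = self.params
        for name in self._trainable():
            g = grads[name].astype(np.float32)
            if momentum > 0.0:
                v = self._vel.get(name)
                if v is None:
                    v = np.zeros_like(params[name])
                v = momentum * v - lr * g
                self._vel[name] = v
                params[name] += v
            else:
                params[name] -= lr * g
        return float(-np.log(p[np.arange(n), y] + 1e-12).mean())

    def predict_scores(self, X, batch: int = 512):
        out = []
        for i in range(0, len(X), batch):
            logits = self._forward(_prep(X[i : i + batch]))
            out.append(_softmax(logits)[:, 1])
        return np.concatenate(out) if out else np.empty(0)


BACKENDS = {
    "smallcnn": SmallCNN,
    "logistic": LogisticBackend,
}


def make_backend(name: str, **kwargs) -> ClassifierBackend:
    if name not in BACKENDS:
        raise CapabilityError(
            f"unknown backend {name!r}; available: {sorted(BACKENDS)}"
        )
    return BACKENDS[name](**kwargs)
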