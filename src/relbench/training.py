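"""Transfer-learning harness: splits, early-stopped training, evaluation.

The protocol mirrors the benchmark's study design: train on a stratified
split, check validation error once per epoch, and stop at the first of a
fixed epoch budget or after the validation error has strictly increased a
configured number of consecutive times (default 6).  The fitted model is the
final-epoch model; no best-checkpoint restoration is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
from PIL import Image

from .backends import ClassifierBackend, CapabilityError
from .datasets import DatasetManifest, TASK_CLASSES
from .render import RenderStyle, TASK_STYLES


class SplitError(ValueError):
    """A class has too few records to stratify."""


@dataclass(frozen=True)
class TrainConfig:
    mode: str = "unrestricted"
    batch_size: int = 50
    learning_rate: float = 1e-3
    max_epochs: int = 10
    patience: int = 6  # consecutive validation-error increases that stop training
    val_fraction: float = 0.2
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingTrace:
    train_errors: list[float] = field(default_factory=list)
    val_errors: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""  # {"max_epochs", "patience"}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvalResult:
    n: int
    accuracy: float
    per_class: dict[str, float]
    confusion: list[list[int]]  # rows true (neg, pos), cols predicted

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


def split_dataset(
    manifest: DatasetManifest,
    val_fraction: float,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[DatasetManifest, DatasetManifest]:
    """Stratified train/validation split; exact per-class proportions."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    rng = rng or np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(manifest.records):
        by_class.setdefault(r.label, []).append(i)
    train_idx, val_idx = [], []
    for label, idx in sorted(by_class.items()):
        if len(idx) < 2:
            raise SplitError(f"class {label!r} has fewer than 2 records")
        idx = np.array(idx)
        rng.shuffle(idx)
        n_val = int(round(val_fraction * len(idx)))
        n_val = min(max(n_val, 1), len(idx) - 1)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    train_idx.sort()
    val_idx.sort()

    def subset(indices, phase_suffix):
        return DatasetManifest(
            task=manifest.task,
            phase=f"{manifest.phase}_{phase_suffix}",
            records=[manifest.records[i] for i in indices],
            frame_px=manifest.frame_px,
            config=manifest.config,
            shape_library=manifest.shape_library,
        )

    return subset(train_idx, "split"), subset(val_idx, "val")


def load_images(
    manifest: DatasetManifest,
    size: Optional[int] = None,
    style: Optional[RenderStyle] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a manifest to ``(X, y)``: float32 images in [0, 1] and int labels."""
    size = size or manifest.frame_px
    imgs = np.empty((len(manifest), size, size, 3), dtype=np.float32)
    for i, rec in enumerate(manifest.records):
        arr = manifest.render(rec, style)
        if size != manifest.frame_px:
            im = Image.fromarray(arr).resize((size, size), Image.BILINEAR)
            arr = np.asarray(im)
        imgs[i] = arr.astype(np.float32) / 255.0
    return imgs, manifest.labels()


DataLike = Union[DatasetManifest, tuple[np.ndarray, np.ndarray]]


def _as_xy(data: DataLike, backend: ClassifierBackend) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, DatasetManifest):
        return load_images(data, size=backend.input_size)
    X, y = data
    return np.asarray(X, dtype=np.float32), np.asarray(y)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def _error_rate(backend: ClassifierBackend, X: np.ndarray, y: np.ndarray) -> float:
    return float((backend.predict(X) != y).mean())


def train_with_early_stopping(
    backend: ClassifierBackend,
    train: DataLike,
    val: DataLike,
    config: TrainConfig,
) -> tuple[ClassifierBackend, TrainingTrace]:
    """SGD with per-epoch validation checks and consecutive-increase stopping.

    An "increase" is a strict increase of validation error relative to the
    immediately preceding epoch's check; ``config.patience`` consecutive
    increases end training.
    """
    backend.set_mode(config.mode)  # raises CapabilityError if unsupported
    X_tr, y_tr = _as_xy(train, backend)
    X_val, y_val = _as_xy(val, backend)
    rng = np.random.default_rng(config.seed)
    trace = TrainingTrace()
    consecutive = 0
    prev_val = None
    for epoch in range(1, config.max_epochs + 1):
        backend.on_epoch_start(epoch)
        order = rng.permutation(len(X_tr))
        batch_errors = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            backend.fit_batch(
                X_tr[sel], y_tr[sel], lr=config.learning_rate,
                momentum=config.momentum,
            )
            if backend.last_batch_error is not None:
                batch_errors.append(backend.last_batch_error)
        if batch_errors:
            trace.train_errors.append(float(np.mean(batch_errors)))
        else:
            trace.train_errors.append(_error_rate(backend, X_tr, y_tr))
        val_err = _error_rate(backend, X_val, y_val)
        trace.val_errors.append(val_err)
        trace.stop_epoch = epoch
        if prev_val is not None and val_err > prev_val:
            consecutive += 1
        else:
            consecutive = 0
        prev_val = val_err
        if consecutive >= config.patience:
            trace.stop_reason = "patience"
            return backend, trace
    trace.stop_reason = "max_epochs"
    return backend, trace


def evaluate(
    model: ClassifierBackend,
    data: DataLike,
    class_names: Optional[tuple[str, str]] = None,
) -> EvalResult:
    """Accuracy, per-class accuracy, and the 2x2 confusion table."""
    if isinstance(data, DatasetManifest):
        if len(data) == 0:
            raise ValueError("empty manifest")
        class_names = class_names or TASK_CLASSES[data.task]
    X, y = _as_xy(data, model)
    if len(X) == 0:
        raise ValueError("no records to evaluate")
    pred = model.predict(X)
    neg, pos = class_names or ("class0", "class1")
    confusion = [
        [int(((y == 0) & (pred == 0)).sum()), int(((y == 0) & (pred == 1)).sum())],
        [int(((y == 1) & (pred == 0)).sum()), int(((y == 1) & (pred == 1)).sum())],
    ]
    per_class = {}
    for cls, name in ((0, neg), (1, pos)):
        m = y == cls
        per_class[name] = float((pred[m] == cls).mean()) if m.any() else float("nan")
    return EvalResult(
        n=len(y),
        accuracy=float((pred == y).mean()),
        per_class=per_class,
        confusion=confusion,
    )
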