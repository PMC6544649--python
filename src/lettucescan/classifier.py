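"""Binary lettuce/background CNN for 20x20 NDVI patches.

The model is a small convolutional network: two 32-filter 3x3 conv blocks
(each ReLU + batch-norm) followed by 2x2 max pooling, two 64-filter blocks
followed by a second pooling, then a 512-unit dense layer with 50% dropout
and a single sigmoid output giving the probability that the patch encloses a
whole lettuce head.  Same-padding keeps the spatial arithmetic exact:
20 -> 20 -> 10 -> 10 -> 5.

Training follows an anti-overfitting protocol: the balanced labelled set is
split 50/50 (stratified, seeded) into train and validation halves, pixel
values are scaled to [0, 1], and training stops at the earliest epoch where
the validation accuracy is at least the training accuracy *and* has plateaued
(improved by less than 0.1 percentage points over the last two epochs), or at
``epochs_max``.  ``online_update`` continues training from the current
weights after new labelled patches — typically from regions where the model
failed, such as very bright or very dark parts of the field — are merged into
the training pool.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .synthetic_field import BOX, LabelledPatch

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "PatchClassifier",
    "build_model",
    "train",
    "predict_patches",
    "online_update",
    "save_model",
    "load_model",
    "patches_to_arrays",
]

_PLATEAU_PP = 0.1       # plateau tolerance, percentage points
_PREDICT_CHUNK = 1024


@dataclass
class ModelConfig:
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: int = 3
    pool: int = 2
    dense_units: int = 512
    dropout: float = 0.5
    epochs_max: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.conv1_filters, self.conv2_filters, self.dense_units,
               self.epochs_max, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("all sizes and the learning rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.kernel != 3 or self.pool != 2:
            raise ValueError("this architecture is fixed to 3x3 kernels and 2x2 pooling")


@dataclass
class TrainingHistory:
    """Per-epoch accuracy/loss curves and the epoch training stopped at."""

    train_acc: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    stopping_epoch: int = 0

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_acc", "val_acc", "train_loss", "val_loss"])
            for i in range(len(self.train_acc)):
                w.writerow([i + 1,
                            f"{self.train_acc[i]:.6f}", f"{self.val_acc[i]:.6f}",
                            f"{self.train_loss[i]:.6f}", f"{self.val_loss[i]:.6f}"])
            w.writerow(["stopping_epoch", self.stopping_epoch, "", "", ""])


class PatchClassifier:
    """The network plus its optimiser state, seeds and training pool."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        init_rng = np.random.default_rng(cfg.seed)
        c1, c2, d = cfg.conv1_filters, cfg.conv2_filters, cfg.dense_units
        self.net = _nn.Network([
            _nn.Conv2D(1, c1, init_rng), _nn.BatchNorm(c1), _nn.ReLU(),
            _nn.Conv2D(c1, c1, init_rng), _nn.BatchNorm(c1), _nn.ReLU(),
            _nn.MaxPool2(),
            _nn.Conv2D(c1, c2, init_rng), _nn.BatchNorm(c2), _nn.ReLU(),
            _nn.Conv2D(c2, c2, init_rng), _nn.BatchNorm(c2), _nn.ReLU(),
            _nn.MaxPool2(),
            _nn.Flatten(),
            _nn.Dense((BOX // 4) ** 2 * c2, d, init_rng), _nn.ReLU(),
            _nn.Dropout(cfg.dropout),
            _nn.Dense(d, 1, init_rng),
        ])
        self.opt = _nn.Adam(self.net.params(), lr=cfg.learning_rate)
        self.rng = np.random.default_rng(cfg.seed + 1)
        self.history = TrainingHistory()
        self.trained = False
        self._train_X = self._train_y = None
        self._val_X = self._val_y = None

    # -- inference -------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities for an (n, 20, 20) float-or-uint8 patch stack."""
        if X.size == 0:
            return np.empty(0)
        return self._predict_scaled(_scale(X))

    def _predict_scaled(self, Xs: np.ndarray) -> np.ndarray:
        out = np.empty(len(Xs))
        for i in range(0, len(Xs), _PREDICT_CHUNK):
            out[i:i + _PREDICT_CHUNK] = self.net.predict_proba(Xs[i:i + _PREDICT_CHUNK])
        return out

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(accuracy, BCE loss) in inference mode."""
        p = self.predict_proba(X)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        acc = np.mean((p >= 0.5) == (y == 1))
        return float(acc), float(loss)


def build_model(cfg: ModelConfig | None = None) -> PatchClassifier:
    """Fresh, seeded, untrained classifier."""
    return PatchClassifier(cfg or ModelConfig())


def patches_to_arrays(patches) -> tuple[np.ndarray, np.ndarray]:
    """Stack LabelledPatch objects into (X, y) arrays."""
    X = np.stack([np.asarray(p.pixels) for p in patches])
    y = np.asarray([p.label for p in patches], dtype=np.float64)
    return X, y


def _scale(X: np.ndarray) -> np.ndarray:
    """To float32 in [0, 1] with a trailing channel axis."""
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[..., None]
    if X.shape[1:3] != (BOX, BOX):
        raise ValueError(f"patches must be {BOX}x{BOX}, got {X.shape[1:3]}")
    return (X.astype(_nn.F32) / _nn.F32(255.0))


def _stratified_half_split(y: np.ndarray, rng: np.random.Generator):
    """50/50 split preserving the class ratio in both halves."""
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        half = len(idx) // 2
        train_idx.append(idx[:half])
        val_idx.append(idx[half:])
    return (rng.permutation(np.concatenate(train_idx)),
            rng.permutation(np.concatenate(val_idx)))


def train(model: PatchClassifier, patches,
          cfg: ModelConfig | None = None) -> tuple[PatchClassifier, TrainingHistory]:
    """Train on a balanced labelled-patch set; returns the model and curves.

    Preconditions: both classes present, class balance within 1 percentage
    point of 50/50, and at least two batches of data.  The model returned is
    the stopping-epoch snapshot: training halts as soon as the stopping rule
    fires, so no later update ever touches the weights.
    """
    cfg = cfg or model.cfg
    X, y = patches_to_arrays(patches) if not isinstance(patches, tuple) else patches
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if abs(float(np.mean(y)) - 0.5) > 0.01:
        raise ValueError("classes must be balanced within 1%")
    if len(y) < 2 * cfg.batch_size:
        raise ValueError(f"need at least {2 * cfg.batch_size} patches")

    split_rng = np.random.default_rng(cfg.seed)
    tr, va = _stratified_half_split(y, split_rng)
    model._train_X, model._train_y = _scale(X[tr]), y[tr]
    model._val_X, model._val_y = _scale(X[va]), y[va]
    _fit(model, cfg)
    return model, model.history


def _fit(model: PatchClassifier, cfg: ModelConfig) -> None:
    """Epoch loop with the validation-governed stopping rule."""
    Xt, yt = model._train_X, model._train_y
    hist = model.history
    base = len(hist.val_acc)       # continuation point for online updates
    for _ in range(cfg.epochs_max):
        order = model.rng.permutation(len(yt))
        batch_accs, batch_losses = [], []
        for s in range(0, len(order) - cfg.batch_size + 1, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            z = model.net.forward(Xt[idx], training=True, rng=model.rng)
            loss, dz = _nn.bce_loss_and_grad(z, yt[idx])
            model.net.backward(dz)
            model.opt.step(model.net.grads())
            p = _nn.sigmoid(z.ravel())
            batch_accs.append(np.mean((p >= 0.5) == (yt[idx] == 1)))
            batch_losses.append(loss)
        pv = model._predict_scaled(model._val_X)
        eps = 1e-12
        yv = model._val_y
        vl = float(-np.mean(yv * np.log(pv + eps) + (1 - yv) * np.log(1 - pv + eps)))
        va = float(np.mean((pv >= 0.5) == (yv == 1)))
        hist.train_acc.append(float(np.mean(batch_accs)))
        hist.train_loss.append(float(np.mean(batch_losses)))
        hist.val_acc.append(va)
        hist.val_loss.append(vl)

        e = len(hist.val_acc) - base          # epochs in this fit
        hist.stopping_epoch = len(hist.val_acc)
        if e >= 3 and va >= hist.train_acc[-1]:
            recent_best = max(hist.val_acc[-3:-1])
            if (va - recent_best) * 100.0 < _PLATEAU_PP:
                break
    model.trained = True


def predict_patches(model: PatchClassifier, patches) -> np.ndarray:
    """Batched head-probability inference for a list/stack of 20x20 patches."""
    if isinstance(patches, np.ndarray):
        X = patches
    else:
        patches = list(patches)
        if not patches:
            return np.empty(0)
        X = np.stack([np.asarray(p.pixels if isinstance(p, LabelledPatch) else p)
                      for p in patches])
    return model.predict_proba(X)


def online_update(model: PatchClassifier, new_patches,
                  cfg: ModelConfig | None = None) -> PatchClassifier:
    """Retrain from the current weights with new labelled data merged in.

    The new patches join the training half (the validation half is kept fixed
    so accuracy remains comparable before and after); optimisation continues
    from the existing Adam state — no re-initialisation — and the history is
    appended to.
    """
    if not model.trained:
        raise ValueError("online_update requires a trained model")
    new_patches = list(new_patches)
    if not new_patches:
        raise ValueError("no new patches supplied")
    cfg = cfg or model.cfg
    Xn, yn = patches_to_arrays(new_patches)
    model._train_X = np.concatenate([model._train_X, _scale(Xn)])
    model._train_y = np.concatenate([model._train_y, yn])
    _fit(model, cfg)
    return model


def save_model(model: PatchClassifier, path) -> None:
    """Persist weights, batch-norm statistics and config as a single .npz."""
    arrays = {f"arr{i}": a for i, a in enumerate(model.net.state_arrays())}
    cfg = model.cfg
    meta = np.array([cfg.conv1_filters, cfg.conv2_filters, cfg.kernel, cfg.pool,
                     cfg.dense_units, cfg.epochs_max, cfg.batch_size, cfg.seed],
                    dtype=np.int64)
    np.savez(path, _meta=meta, _dropout=cfg.dropout, _lr=cfg.learning_rate,
             **arrays)


def load_model(path) -> PatchClassifier:
    with np.load(path) as data:
        m = data["_meta"]
        cfg = ModelConfig(conv1_filters=int(m[0]), conv2_filters=int(m[1]),
                          kernel=int(m[2]), pool=int(m[3]), dense_units=int(m[4]),
                          epochs_max=int(m[5]), batch_size=int(m[6]),
                          dropout=float(data["_dropout"]),
                          learning_rate=float(data["_lr"]), seed=int(m[7]))
        model = build_model(cfg)
        for i, a in enumerate(model.net.state_arrays()):
            a[...] = data[f"arr{i}"]
    model.trained = True
    return model
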