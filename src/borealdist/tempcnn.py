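"""1-D temporal convolutional classifier for 10-year x 6-band windows.

Architecture: stacked Conv1D blocks (64 filters, kernel 3, same padding,
ReLU, dropout 0.4) along the time axis, flatten, one dense layer of width 64
with ReLU and dropout, softmax output. Trained with Adam, cross-entropy,
batch 64, 50 epochs, L2 weight decay 1e-5 and a multiplicatively decaying
learning rate starting at 1e-3.

Implemented in numpy (forward and backward passes by hand) so the package
has no deep-learning framework dependency; training is deterministic under a
fixed seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import N_CLASSES
from .spectral import ValidationError


@dataclass
class ModelConfig:
    n_timesteps: int = 10
    n_bands: int = 6
    n_filters: int = 64
    kernel_size: int = 3
    dense_units: int = 64
    dropout: float = 0.4
    n_conv_blocks: int = 3
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.n_timesteps < self.kernel_size:
            raise ValidationError("window shorter than the convolution kernel")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    weight_decay: float = 1e-5
    initial_lr: float = 1e-3
    lr_decay: float = 0.95  # multiplicative, applied each epoch
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.initial_lr <= 0:
            raise ValidationError("epochs, batch_size and initial_lr must be positive")


class Normalizer:
    """Per-band standardization fitted on training windows, stored with the model."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.std = np.where(np.asarray(std, dtype=float) < 1e-8, 1.0, std)

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalizer":
        return cls(X.mean(axis=(0, 1)), X.std(axis=(0, 1)))

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def _unfold(xp: np.ndarray) -> np.ndarray:
    # xp: (B, T+2, C) padded; returns (B, T, 3C) kernel-3 patches
    return np.concatenate([xp[:, :-2], xp[:, 1:-1], xp[:, 2:]], axis=2)


def _fold(d: np.ndarray, t: int, c: int) -> np.ndarray:
    # adjoint of _unfold: d (B, T, 3C) -> gradient w.r.t. padded input (B, T+2, C)
    out = np.zeros((d.shape[0], t + 2, c))
    out[:, :-2] += d[:, :, :c]
    out[:, 1:-1] += d[:, :, c:2 * c]
    out[:, 2:] += d[:, :, 2 * c:]
    return out


class TempCNN:
    """The classifier; see module docstring for the topology."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        c = self.cfg
        self.params: dict[str, np.ndarray] = {}
        in_ch = c.n_bands
        for b in range(c.n_conv_blocks):
            fan_in = c.kernel_size * in_ch
            self.params[f"Wc{b}"] = rng.normal(0, np.sqrt(2 / fan_in), (fan_in, c.n_filters))
            self.params[f"bc{b}"] = np.zeros(c.n_filters)
            in_ch = c.n_filters
        flat = c.n_timesteps * c.n_filters
        self.params["Wd"] = rng.normal(0, np.sqrt(2 / flat), (flat, c.dense_units))
        self.params["bd"] = np.zeros(c.dense_units)
        self.params["Wo"] = rng.normal(0, np.sqrt(2 / c.dense_units), (c.dense_units, c.n_classes))
        self.params["bo"] = np.zeros(c.n_classes)
        self.normalizer: Normalizer | None = None

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward / backward ------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None):
        c = self.cfg
        keep = 1.0 - c.dropout
        cache: dict = {"a": [], "mask": [], "col": []}
        a = X
        for b in range(c.n_conv_blocks):
            pad = np.pad(a, ((0, 0), (1, 1), (0, 0)))
            col = _unfold(pad)
            z = col @ self.params[f"Wc{b}"] + self.params[f"bc{b}"]
            act = np.maximum(z, 0.0)
            if train and c.dropout > 0:
                mask = (rng.random(act.shape) < keep) / keep
                act *= mask
            else:
                mask = None
            cache["col"].append(col)
            cache["a"].append(act)
            cache["mask"].append(mask)
            a = act
        flat = a.reshape(a.shape[0], -1)
        zd = flat @ self.params["Wd"] + self.params["bd"]
        ad = np.maximum(zd, 0.0)
        if train and c.dropout > 0:
            md = (rng.random(ad.shape) < keep) / keep
            ad = ad * md
        else:
            md = None
        logits = ad @ self.params["Wo"] + self.params["bo"]
        cache.update(flat=flat, ad=ad, md=md, X=X)
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        c = self.cfg
        g: dict[str, np.ndarray] = {}
        g["Wo"] = cache["ad"].T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        dad = dlogits @ self.params["Wo"].T
        if cache["md"] is not None:
            dad = dad * cache["md"]
        dzd = dad * (cache["ad"] > 0)
        g["Wd"] = cache["flat"].T @ dzd
        g["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        da = dflat.reshape(cache["a"][-1].shape)
        for b in range(c.n_conv_blocks - 1, -1, -1):
            act, mask, col = cache["a"][b], cache["mask"][b], cache["col"][b]
            if mask is not None:
                da = da * mask
            dz = da * (act > 0)
            g[f"Wc{b}"] = col.reshape(-1, col.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
            g[f"bc{b}"] = dz.sum(axis=(0, 1))
            if b > 0:
                dcol = dz @ self.params[f"Wc{b}"].T
                in_ch = c.n_filters
                dpad = _fold(dcol, cache["a"][b - 1].shape[1], in_ch)
                da = dpad[:, 1:-1]
        return g

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for windows of shape (10, 6) or (B, 10, 6)."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        c = self.cfg
        if X.shape[1:] != (c.n_timesteps, c.n_bands):
            raise ValidationError(
                f"windows must be (B, {c.n_timesteps}, {c.n_bands}), got {X.shape}"
            )
        if self.normalizer is not None:
            X = self.normalizer(X)
        logits, _ = self._forward(X, train=False)
        probs = _softmax(logits)
        return probs[0] if single else probs

    def predict(self, X: np.ndarray) -> np.ndarray | int:
        """Argmax class index; ties break to the lowest index."""
        probs = self.predict_proba(X)
        return int(np.argmax(probs)) if probs.ndim == 1 else np.argmax(probs, axis=1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> TempCNN:
    """Deterministically initialize a classifier from its configuration."""
    return TempCNN(cfg, seed=seed)


def train_model(
    model: TempCNN,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
) -> list[float]:
    """Fit in place with Adam + cross-entropy; returns per-epoch mean losses.

    Fits the per-band normalizer on X and stores it on the model.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 3 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be (n, 10, 6) aligned with y")
    if np.unique(y).size < 2:
        raise ValidationError("training requires at least 2 classes")

    model.normalizer = Normalizer.fit(X)
    Xn = model.normalizer(X)
    n, n_classes = X.shape[0], model.cfg.n_classes
    rng = np.random.default_rng(cfg.seed)

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    lr = cfg.initial_lr
    losses = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = Xn[idx], y[idx]
            logits, cache = model._forward(xb, train=True, rng=rng)
            probs = _softmax(logits)
            batch = idx.size
            epoch_loss += -np.log(probs[np.arange(batch), yb] + 1e-12).sum()
            dlogits = probs.copy()
            dlogits[np.arange(batch), yb] -= 1.0
            dlogits /= batch
            grads = model._backward(dlogits, cache)
            step += 1
            for k, p in model.params.items():
                gk = grads[k] + cfg.weight_decay * p
                m[k] = beta1 * m[k] + (1 - beta1) * gk
                v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        lr *= cfg.lr_decay
        losses.append(epoch_loss / n)
    assert n_classes >= 2
    return losses


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    tile_ids: np.ndarray,
    split_plan,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[TempCNN, pd.DataFrame]:
    """Spatial cross-validation then a final fit on all points.

    For each fold a fresh model is trained on the train-tile examples and
    evaluated on the test-tile examples; holdout-tile accuracy is reported
    alongside as an overfitting check. Returns the final model (trained on
    every example) and a per-fold metric table.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    tile_ids = np.asarray(tile_ids)
    hold_mask = np.isin(tile_ids, split_plan.holdout_tiles)
    rows = []
    for f, (train_tiles, test_tiles) in enumerate(split_plan.folds):
        tr = np.isin(tile_ids, train_tiles)
        te = np.isin(tile_ids, test_tiles)
        absent = np.setdiff1d(np.unique(y), np.unique(y[tr]))
        if absent.size:
            warnings.warn(
                f"fold {f}: classes {absent.tolist()} absent from training tiles; "
                "they are dropped from this fold's metrics",
                stacklevel=2,
            )
        fold_model = build_model(model_cfg, seed=train_cfg.seed + f)
        fold_cfg = TrainConfig(
            epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
            weight_decay=train_cfg.weight_decay, initial_lr=train_cfg.initial_lr,
            lr_decay=train_cfg.lr_decay, seed=train_cfg.seed + f,
        )
        train_model(fold_model, X[tr], y[tr], fold_cfg)
        rows.append({
            "fold": f,
            "train_accuracy": accuracy(fold_model, X[tr], y[tr]),
            "test_accuracy": accuracy(fold_model, X[te], y[te]),
            "holdout_accuracy": accuracy(fold_model, X[hold_mask], y[hold_mask]),
            "n_train": int(tr.sum()),
            "n_test": int(te.sum()),
        })
    final = build_model(model_cfg, seed=train_cfg.seed)
    train_model(final, X, y, train_cfg)
    return final, pd.DataFrame(rows)


def accuracy(model: TempCNN, X: np.ndarray, y: np.ndarray) -> float:
    if len(y) == 0:
        return float("nan")
    return float(np.mean(model.predict(X) == np.asarray(y)))


def per_class_recall(model: TempCNN, X: np.ndarray, y: np.ndarray) -> dict[int, float]:
    pred = model.predict(X)
    y = np.asarray(y)
    return {
        int(c): float(np.mean(pred[y == c] == c))
        for c in np.unique(y)
    }
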