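"""The residual CNN sepsis classifier and its training regimen.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) so it composes with pipelines and model
selection.  Architecture: an initial 1-D convolution and max-pool, eight
identity blocks each followed by a max-pool, then a 100-unit dense layer,
dropout, and a 2-unit softmax head.  Training uses Adam with binary
cross-entropy (softmax cross-entropy over the two classes), and the weights
with the lowest validation loss across epochs are retained.

Reference hyperparameters: 40 filters of width 3, learning rate 1e-6, batch
size 128, 800 epochs.  These suit long GPU training runs; desk-scale work
passes smaller ``epochs`` / ``n_filters`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import Adam, ResNet1D, softmax_cross_entropy

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "AugmentConfig",
    "TrainedFold",
    "normalize_segment",
    "augment_jitter",
    "augment_random_window",
    "ResNet1DClassifier",
    "train_fold",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters."""

    n_identity_blocks: int = 8
    n_filters: int = 40
    kernel_width: int = 3
    dense_units: int = 100
    dropout_rate: float = 0.2
    pool_size: int = 2
    init_scheme: str = "glorot-uniform"
    input_length: int = 15000


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    learning_rate: float = 1e-6
    batch_size: int = 128
    epochs: int = 800
    optimizer: str = "adam"
    loss: str = "binary-cross-entropy"
    seed: int = 0


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentations (both disabled by default)."""

    jitter_enabled: bool = False
    jitter_std: float = 0.05
    jitter_prob: float = 0.5
    window_enabled: bool = False
    window_s: float = 90.0


@dataclass
class TrainedFold:
    """Result of training on one cross-validation fold."""

    fold_id: int
    weights_ref: "ResNet1DClassifier"
    best_val_loss: float
    history: List[Tuple[float, float]]  # (train_loss, val_loss) per epoch


def normalize_segment(samples: Sequence[float]) -> np.ndarray:
    """Affine min-max map onto [-1, 1] (min -> -1, max -> +1).

    Constant input cannot be normalized and raises; quality control rejects
    constant windows upstream.
    """
    x = np.asarray(samples, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant signal")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def augment_jitter(samples: np.ndarray, std: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Add Gaussian noise, then renormalize back to exactly [-1, 1]."""
    if std == 0:
        return np.asarray(samples, dtype=np.float64).copy()
    noisy = np.asarray(samples, dtype=np.float64) + rng.normal(0.0, std, size=len(samples))
    return normalize_segment(noisy)


def augment_random_window(samples: np.ndarray, fs: float, window_s: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Contiguous random sub-window of ``window_s`` seconds."""
    x = np.asarray(samples)
    n = int(round(window_s * fs))
    if n > x.size:
        raise ValueError("window longer than the segment")
    start = int(rng.integers(0, x.size - n + 1))
    return x[start:start + n]


def _center_crop(x: np.ndarray, n: int) -> np.ndarray:
    start = (x.shape[-1] - n) // 2
    return x[..., start:start + n]


class ResNet1DClassifier(BaseEstimator, ClassifierMixin):
    """1-D residual CNN for two-class PPG segment classification.

    Parameters mirror :class:`ModelConfig`, :class:`TrainConfig` and
    :class:`AugmentConfig`.  ``fit`` accepts an optional validation set;
    when provided, per-epoch validation loss is recorded and the weights
    with the lowest validation loss are restored at the end ("best weights"
    selection).  When ``groups`` / ``val_groups`` (subject identifiers) are
    given, subject overlap between training and validation raises.

    Attributes
    ----------
    net_ : the fitted network
    classes_ : class labels (positive class = ``classes_[1]``)
    history_ : list of (train_loss, val_loss) per epoch (val NaN if no val set)
    best_val_loss_ : minimum validation loss across epochs
    n_parameters_ : trainable parameter count
    """

    def __init__(
        self,
        n_identity_blocks: int = 8,
        n_filters: int = 40,
        kernel_width: int = 3,
        dense_units: int = 100,
        dropout_rate: float = 0.2,
        pool_size: int = 2,
        input_length: int = 15000,
        learning_rate: float = 1e-6,
        batch_size: int = 128,
        epochs: int = 800,
        jitter_enabled: bool = False,
        jitter_std: float = 0.05,
        jitter_prob: float = 0.5,
        window_enabled: bool = False,
        window_s: float = 90.0,
        fs: float = 125.0,
        random_state: Optional[int] = None,
    ):
        self.n_identity_blocks = n_identity_blocks
        self.n_filters = n_filters
        self.kernel_width = kernel_width
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.pool_size = pool_size
        self.input_length = input_length
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.jitter_enabled = jitter_enabled
        self.jitter_std = jitter_std
        self.jitter_prob = jitter_prob
        self.window_enabled = window_enabled
        self.window_s = window_s
        self.fs = fs
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _effective_input_length(self) -> int:
        # With random-window augmentation the network is built at the window
        # length and non-augmented inputs are center-cropped to match.
        if self.window_enabled:
            return int(round(self.window_s * self.fs))
        return self.input_length

    def _build(self, rng: np.random.Generator) -> ResNet1D:
        return ResNet1D(
            input_length=self._effective_input_length(),
            n_identity_blocks=self.n_identity_blocks,
            n_filters=self.n_filters,
            kernel_width=self.kernel_width,
            dense_units=self.dense_units,
            dropout_rate=self.dropout_rate,
            pool_size=self.pool_size,
            rng=rng,
        )

    def _augment_batch(self, xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n_out = self._effective_input_length()
        out = np.empty((xb.shape[0], n_out), dtype=np.float64)
        for i in range(xb.shape[0]):
            x = xb[i]
            if self.window_enabled:
                x = augment_random_window(x, self.fs, self.window_s, rng)
            if self.jitter_enabled and rng.uniform() < self.jitter_prob:
                x = augment_jitter(x, self.jitter_std, rng)
            out[i] = x if x.size == n_out else _center_crop(x, n_out)
        return out

    def fit(self, X, y, X_val=None, y_val=None,
            groups: Optional[Sequence] = None,
            val_groups: Optional[Sequence] = None) -> "ResNet1DClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_segments, n_samples)")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if X.shape[1] != self.input_length:
            raise ValueError(
                f"expected segments of length {self.input_length}, got {X.shape[1]}"
            )
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val = np.asarray(y_val)
            if X_val.shape[0] == 0:
                raise ValueError("empty validation set")
            if groups is not None and val_groups is not None:
                overlap = set(map(str, groups)) & set(map(str, val_groups))
                if overlap:
                    raise ValueError(
                        f"subject overlap between train and validation: {sorted(overlap)[:5]}"
                    )

        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("exactly two classes are required")
        rng = np.random.default_rng(self.random_state)
        net = self._build(rng)
        opt = Adam(net.parameters(), lr=self.learning_rate)
        n_eff = self._effective_input_length()

        if X_val is not None:
            Xv = X_val if X_val.shape[1] == n_eff else _center_crop(X_val, n_eff)
            yv_idx = np.searchsorted(self.classes_, y_val)

        history: List[Tuple[float, float]] = []
        best_val = np.inf
        best_weights = None
        n = X.shape[0]
        augment = self.jitter_enabled or self.window_enabled
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for i in range(0, n, self.batch_size):
                idx = order[i:i + self.batch_size]
                xb = X[idx]
                xb = self._augment_batch(xb, rng) if augment else (
                    xb if xb.shape[1] == n_eff else _center_crop(xb, n_eff))
                logits = net.forward(xb, training=True)
                loss, dlogits = softmax_cross_entropy(logits, y_idx[idx])
                net.backward(dlogits)
                opt.step()
                epoch_losses.append(loss)
            train_loss = float(np.mean(epoch_losses))
            if X_val is not None:
                val_loss = self._loss_of(net, Xv, yv_idx)
                if val_loss < best_val:
                    best_val = val_loss
                    best_weights = net.get_weights()
            else:
                val_loss = float("nan")
            history.append((train_loss, val_loss))

        if best_weights is not None:
            net.set_weights(best_weights)
        self.net_ = net
        self.history_ = history
        self.best_val_loss_ = best_val if np.isfinite(best_val) else float("nan")
        self.n_parameters_ = net.n_parameters()
        return self

    @staticmethod
    def _loss_of(net: ResNet1D, X: np.ndarray, y_idx: np.ndarray,
                 batch_size: int = 256) -> float:
        total, count = 0.0, 0
        for i in range(0, X.shape[0], batch_size):
            logits = net.forward(X[i:i + batch_size], training=False)
            loss, _ = softmax_cross_entropy(logits, y_idx[i:i + batch_size])
            total += loss * logits.shape[0]
            count += logits.shape[0]
        return total / count

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        n_eff = self.net_.cfg["input_length"]
        if X.shape[1] != n_eff:
            if X.shape[1] == self.input_length and self.window_enabled:
                X = _center_crop(X, n_eff)
            else:
                raise ValueError(
                    f"expected input length {n_eff} (or {self.input_length}), got {X.shape[1]}"
                )
        return self.net_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    def score_sepsis(self, X) -> np.ndarray:
        """Probability of the positive (second) class per segment."""
        return self.predict_proba(X)[:, 1]

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        """Write weights (``.npz``) plus a JSON sidecar with the configuration."""
        import json
        from pathlib import Path

        path = Path(path)
        weights = self.net_.get_weights()
        np.savez_compressed(path, *weights, classes=np.asarray(self.classes_))
        sidecar = {"params": self.get_params(),
                   "best_val_loss": float(self.best_val_loss_)
                   if np.isfinite(self.best_val_loss_) else None,
                   "history": self.history_}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "ResNet1DClassifier":
        """Restore a fitted classifier written by :meth:`save`."""
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        clf = cls(**sidecar["params"])
        with np.load(path if path.suffix == ".npz" else f"{path}.npz",
                     allow_pickle=False) as z:
            clf.classes_ = z["classes"]
            weights = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
        net = clf._build(np.random.default_rng(0))
        net.set_weights(weights)
        clf.net_ = net
        clf.history_ = [tuple(h) for h in sidecar["history"]]
        clf.best_val_loss_ = (sidecar["best_val_loss"]
                              if sidecar["best_val_loss"] is not None else float("nan"))
        clf.n_parameters_ = net.n_parameters()
        return clf


def train_fold(
    train_segments: Tuple[np.ndarray, np.ndarray],
    val_segments: Tuple[np.ndarray, np.ndarray],
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    aug_cfg: AugmentConfig = AugmentConfig(),
    fold_id: int = 0,
    train_subjects: Optional[Sequence] = None,
    val_subjects: Optional[Sequence] = None,
) -> TrainedFold:
    """Train one cross-validation fold and return the best-by-validation model.

    ``train_segments`` / ``val_segments`` are ``(X, y)`` pairs of normalized
    segments and labels.  Subject sequences, when given, are checked for
    train/validation disjointness.
    """
    clf = ResNet1DClassifier(
        n_identity_blocks=model_cfg.n_identity_blocks,
        n_filters=model_cfg.n_filters,
        kernel_width=model_cfg.kernel_width,
        dense_units=model_cfg.dense_units,
        dropout_rate=model_cfg.dropout_rate,
        pool_size=model_cfg.pool_size,
        input_length=model_cfg.input_length,
        learning_rate=train_cfg.learning_rate,
        batch_size=train_cfg.batch_size,
        epochs=train_cfg.epochs,
        jitter_enabled=aug_cfg.jitter_enabled,
        jitter_std=aug_cfg.jitter_std,
        jitter_prob=aug_cfg.jitter_prob,
        window_enabled=aug_cfg.window_enabled,
        window_s=aug_cfg.window_s,
        random_state=train_cfg.seed,
    )
    clf.fit(train_segments[0], train_segments[1],
            X_val=val_segments[0], y_val=val_segments[1],
            groups=train_subjects, val_groups=val_subjects)
    return TrainedFold(fold_id=fold_id, weights_ref=clf,
                       best_val_loss=clf.best_val_loss_, history=clf.history_)
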