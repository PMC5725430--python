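"""A small convolutional network for image-like EEG tensors, in NumPy.

Architecture (single block): a convolutional layer of 30 8x8 filters
applied identically to each input plane (depthwise with shared weights, so
the mode dimension passes through unaltered), ReLU, 3x3 max-pooling with
stride 2, then one fully connected layer and softmax with cross-entropy
loss.  For the default 256 x 128 input the dimension chain is

    conv:  (256-8)+1 = 249 space  x  (128-8)+1 = 121 time
    pool:  (249-3)/2+1 = 124      x  (121-3)/2+1 = 60

Convolution is GEMM-based (im2col), gradients are exact
analytic expressions (verified against finite differences in the test
suite), and the optimizer is Adam.  Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "CNNConfig",
    "SplitPlan",
    "conv_out_len",
    "pool_out_len",
    "build_model",
    "ConvNet",
    "make_splits",
    "train",
]


class CNNError(ValueError):
    """Invalid network configuration or input."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def conv_out_len(n_in: int, k: int) -> int:
    """Valid-convolution output length: (n_in - k) + 1, stride 1."""
    if not 1 <= k <= n_in:
        raise CNNError(f"kernel {k} exceeds input length {n_in}")
    return n_in - k + 1


def pool_out_len(n_in: int, p: int = 3, stride: int = 2) -> int:
    """Pooled output length: floor((n_in - p) / stride) + 1."""
    if n_in < p:
        raise CNNError(f"pool window {p} exceeds input length {n_in}")
    return (n_in - p) // stride + 1


@dataclass
class CNNConfig:
    """Architecture plus training hyperparameters.

    The architecture fields reproduce the single-block network: 30 filters
    of 8x8, 3x3 max-pool with stride 2, a fully connected softmax head with
    2 or 4 classes.  Optimizer settings (Adam, learning rate 1e-3) are
    conventional choices; the per-fold epoch budget is deliberately small
    because the tensors are large and one CPU is assumed.
    """

    n_filters: int = 30
    kernel: tuple[int, int] = (8, 8)
    pool: tuple[int, int] = (3, 3)
    pool_stride: int = 2
    n_classes: int = 2
    learning_rate: float = 1e-3
    epochs: int = 30
    cv_epochs: int | None = None  # per-fold budget; None -> same as epochs
    batch_size: int = 16
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 4):
            raise CNNError("n_classes must be 2 or 4")
        if min(self.kernel) < 1 or min(self.pool) < 1 or self.pool_stride < 1:
            raise CNNError("kernel/pool dimensions must be positive")


@dataclass
class SplitPlan:
    """Test holdout plus stratified cross-validation folds over the rest."""

    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    train_idx: np.ndarray  # all non-test indices
    n_folds: int = 10
    test_fraction: float = 0.25


def make_splits(labels, seed: int = 0, test_fraction: float = 0.25,
                n_folds: int = 10) -> SplitPlan:
    """Stratified 75/25 train/test split, then stratified k folds.

    ``labels`` may be a sequence of class labels or a
    :class:`~swdeeg.simulate.LabeledDataset`.
    """
    y = np.asarray(getattr(labels, "labels", labels))
    n = y.shape[0]
    if n < 40:
        raise CNNError(f"need at least 40 trials to split, got {n}")
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed)
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    counts = np.unique(y[train_idx], return_counts=True)[1]
    if counts.min() < n_folds:
        raise CNNError(
            f"a class has only {counts.min()} training trials; "
            f"cannot form {n_folds} stratified folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(train_idx[tr], train_idx[va])
             for tr, va in skf.split(train_idx, y[train_idx])]
    return SplitPlan(test_idx=test_idx, folds=folds, train_idx=train_idx,
                     n_folds=n_folds, test_fraction=test_fraction)


# ---------------------------------------------------------------------------
# the network

class ConvNet:
    """conv(30 x 8x8, plane-shared) -> ReLU -> maxpool 3x3/2 -> FC -> softmax."""

    def __init__(self, cfg: CNNConfig, n_channels: int, n_samples: int,
                 n_planes: int = 3, dtype=np.float32):
        self.cfg = cfg
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.n_planes = n_planes
        self.dtype = dtype
        kh, kw = cfg.kernel
        self.hc = conv_out_len(n_channels, kh)
        self.wc = conv_out_len(n_samples, kw)
        self.hp = pool_out_len(self.hc, cfg.pool[0], cfg.pool_stride)
        self.wp = pool_out_len(self.wc, cfg.pool[1], cfg.pool_stride)
        n_flat = n_planes * cfg.n_filters * self.hp * self.wp

        rng = np.random.default_rng(cfg.seed)
        fan_in = kh * kw
        self.W = (rng.standard_normal((cfg.n_filters, kh, kw))
                  * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(cfg.n_filters, dtype=dtype)
        self.W2 = (rng.standard_normal((n_flat, cfg.n_classes))
                   * np.sqrt(2.0 / n_flat)).astype(dtype)
        self.b2 = np.zeros(cfg.n_classes, dtype=dtype)
        self._adam_state: dict | None = None

    # -- forward ------------------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        expected = (self.n_planes, self.n_channels, self.n_samples)
        if X.ndim != 4 or X.shape[1:] != expected:
            raise CNNError(
                f"expected input (batch, {expected[0]}, {expected[1]}, "
                f"{expected[2]}), got {X.shape}"
            )
        return X.astype(self.dtype, copy=False)

    def _im2col(self, X: np.ndarray) -> np.ndarray:
        """(B, P, hc*wc, kh*kw) patch matrix for GEMM-based convolution."""
        kh, kw = self.cfg.kernel
        win = np.lib.stride_tricks.sliding_window_view(X, (kh, kw), axis=(2, 3))
        B, P = X.shape[:2]
        return np.ascontiguousarray(win).reshape(B, P, self.hc * self.wc, kh * kw)

    def _conv(self, X: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        """Valid cross-correlation of every plane with every filter (GEMM)."""
        if cols is None:
            cols = self._im2col(X)
        B, P = cols.shape[:2]
        Wflat = self.W.reshape(self.cfg.n_filters, -1).T      # (kh*kw, F)
        out = cols @ Wflat                                    # (B,P,hc*wc,F)
        out = np.moveaxis(out, -1, 2).reshape(
            B, P, self.cfg.n_filters, self.hc, self.wc)
        return out + self.b[None, None, :, None, None]

    def _pool_slices(self, A: np.ndarray):
        """The ph*pw strided views of A underlying each pooling window cell."""
        ph, pw = self.cfg.pool
        st = self.cfg.pool_stride
        hspan = (self.hp - 1) * st + 1
        wspan = (self.wp - 1) * st + 1
        for dr in range(ph):
            for dc in range(pw):
                yield A[..., dr:dr + hspan:st, dc:dc + wspan:st]

    def _pool(self, A: np.ndarray) -> np.ndarray:
        """3x3/stride-2 max pooling via a max-reduce over window offsets."""
        out = None
        for sl in self._pool_slices(A):
            out = sl.copy() if out is None else np.maximum(out, sl, out=out)
        return out

    def forward(self, X: np.ndarray, want_cache: bool = False):
        X = self._check_input(X)
        cols = self._im2col(X) if want_cache else None
        conv = self._conv(X, cols)
        A = np.maximum(conv, 0.0)
        pooled = self._pool(A)
        flat = pooled.reshape(X.shape[0], -1)
        logits = flat @ self.W2 + self.b2
        if want_cache:
            return logits, (cols, conv, A, pooled, flat)
        return logits

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        X = np.asarray(X)
        out = []
        for i in range(0, X.shape[0], batch_size):
            logits = self.forward(X[i:i + batch_size])
            out.append(_softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class (ties break toward the lower index)."""
        return np.argmax(self.predict_proba(X), axis=1)

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Cross-entropy loss and exact gradients for one batch."""
        logits, (cols, conv, A, pooled, flat) = self.forward(X, want_cache=True)
        B = conv.shape[0]
        probs = _softmax(logits)
        eps = np.finfo(self.dtype).tiny
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))

        dlogits = probs
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        gW2 = flat.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dflat = dlogits @ self.W2.T
        dpool = dflat.reshape(pooled.shape)

        # unpool: route each pooled gradient to the first window cell that
        # achieved the max (exact ties among positive activations are
        # measure-zero; ties at ReLU zeros are annihilated by the ReLU mask)
        dA = np.zeros_like(A)
        claimed = np.zeros(pooled.shape, dtype=bool)
        for a_sl, d_sl in zip(self._pool_slices(A), self._pool_slices(dA)):
            hit = (a_sl == pooled) & ~claimed
            d_sl += dpool * hit
            claimed |= hit
        dconv = dA * (conv > 0.0)

        gb = dconv.sum(axis=(0, 1, 3, 4))
        kh, kw = self.cfg.kernel
        # dW[f, k] = sum over batch/planes/positions of patch[k] * dconv[f]
        F = self.cfg.n_filters
        P = self.n_planes
        dmat = np.ascontiguousarray(
            np.moveaxis(dconv.reshape(B, P, F, -1), 2, 3))  # (B,P,hc*wc,F)
        gW = (cols.reshape(-1, kh * kw).T @ dmat.reshape(-1, F)).T.reshape(
            F, kh, kw).astype(self.dtype)

        if not np.isfinite(loss):
            raise DivergenceError(
                f"non-finite loss (lr={self.cfg.learning_rate})")
        return loss, {"W": gW, "b": gb.astype(self.dtype),
                      "W2": gW2.astype(self.dtype), "b2": gb2.astype(self.dtype)}

    # -- optimizer ----------------------------------------------------------

    def adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999,
                  eps=1e-8) -> None:
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                **{f"m_{k}": np.zeros_like(getattr(self, k)) for k in grads},
                **{f"v_{k}": np.zeros_like(getattr(self, k)) for k in grads},
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for k, g in grads.items():
            g = g.astype(getattr(self, k).dtype, copy=False)
            st[f"m_{k}"] = beta1 * st[f"m_{k}"] + (1 - beta1) * g
            st[f"v_{k}"] = beta2 * st[f"v_{k}"] + (1 - beta2) * g * g
            mhat = st[f"m_{k}"] / (1 - beta1**t)
            vhat = st[f"v_{k}"] / (1 - beta2**t)
            setattr(self, k, getattr(self, k) - lr * mhat / (np.sqrt(vhat) + eps))

    def get_weights(self) -> dict:
        return {k: getattr(self, k).copy() for k in ("W", "b", "W2", "b2")}

    def set_weights(self, weights: dict) -> None:
        for k, v in weights.items():
            setattr(self, k, v.copy())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(cfg: CNNConfig, n_channels: int = 256, n_samples: int = 128,
                n_planes: int = 3, dtype=np.float32) -> ConvNet:
    """Instantiate the network for a given input geometry."""
    return ConvNet(cfg, n_channels, n_samples, n_planes, dtype=dtype)


# ---------------------------------------------------------------------------
# training

def _fit(model: ConvNet, X: np.ndarray, y: np.ndarray,
         Xval: np.ndarray | None, yval: np.ndarray | None,
         rng: np.random.Generator) -> list[dict]:
    """Mini-batch Adam with optional early stopping on validation loss."""
    cfg = model.cfg
    history: list[dict] = []
    best_val = np.inf
    best_weights = None
    bad_epochs = 0
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            loss, grads = model.loss_and_grads(X[sel], y[sel])
            model.adam_step(grads, cfg.learning_rate)
            losses.append(loss)
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if Xval is not None:
            proba = model.predict_proba(Xval)
            eps = 1e-12
            val_loss = float(-np.mean(np.log(
                proba[np.arange(len(yval)), yval] + eps)))
            rec["val_loss"] = val_loss
            rec["val_accuracy"] = float(np.mean(proba.argmax(1) == yval))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = model.get_weights()
                bad_epochs = 0
            else:
                bad_epochs += 1
        history.append(rec)
        if Xval is not None and bad_epochs >= cfg.patience:
            break
    if best_weights is not None:
        model.set_weights(best_weights)
    return history


def train(cfg: CNNConfig, plan: SplitPlan, X: np.ndarray, y: np.ndarray,
          cross_validate: bool = True):
    """Train per-fold models (10-fold CV) and a final model on all training
    data.

    Returns ``(final_model, fold_metrics, history)`` where ``fold_metrics``
    holds each fold's last validation accuracy/loss.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    n_planes, n_channels, n_samples = X.shape[1:]
    fold_metrics: list[dict] = []
    if cross_validate:
        from dataclasses import replace
        fold_cfg = (cfg if cfg.cv_epochs is None
                    else replace(cfg, epochs=cfg.cv_epochs))
        for f, (tr, va) in enumerate(plan.folds):
            model = ConvNet(fold_cfg, n_channels, n_samples, n_planes)
            rng = np.random.default_rng(cfg.seed + 101 * (f + 1))
            hist = _fit(model, X[tr], y[tr], X[va], y[va], rng)
            last = hist[-1]
            best = max(h.get("val_accuracy", 0.0) for h in hist)
            fold_metrics.append({
                "fold": f,
                "val_accuracy": best,
                "val_loss": min(h.get("val_loss", np.inf) for h in hist),
                "epochs_run": last["epoch"] + 1,
                "val_accuracy_by_epoch": [h["val_accuracy"] for h in hist],
            })
    final = ConvNet(cfg, n_channels, n_samples, n_planes)
    rng = np.random.default_rng(cfg.seed)
    history = _fit(final, X[plan.train_idx], y[plan.train_idx], None, None, rng)
    return final, fold_metrics, history
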