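"""The EEG phase prediction network (EPN).

A deliberately small per-subject network that maps 250 first-order
differences of raw EEG (the causal 0.5 s before "time 0" at 500 Hz)
directly to a 2-vector Z interpreted as a complex number whose angle is the
predicted instantaneous phase:

    A = avg_pool(x, s)                    moving average, repeat-padded tail
    F = relu(W A + B)                     fully connected, 500 units
    C = dropout(F, P)                     train-time only, inverted scaling
    Z = U C + D                           2-dim output (Re, Im)

Training regresses Z onto the unit phasor (cos theta, sin theta) of the
ground-truth phase with a mean-squared-error loss and the Adam optimizer.
The forward/backward passes and optimizer are explicit numpy; the whole
model is a few matrices, so nothing heavier is warranted and every step is
reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._utils import wrap_phase

__all__ = [
    "EPNConfig",
    "EPNWeights",
    "avg_pool",
    "forward",
    "phase_from_output",
    "predict_phase",
    "train",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class EPNConfig:
    """Architecture and optimization hyperparameters.

    The canonical values (3000 epochs, lr 1e-5, batch 512, dropout 0.9,
    kernel 13, hidden 500) are the full-scale training schedule; for
    desk-scale runs use :meth:`desk_scale`, which shortens the schedule to
    300 epochs with the standard Adam rate 1e-3.
    """

    input_len: int = 250
    pool_kernel: int = 13
    hidden_dim: int = 500
    dropout_p: float = 0.9
    lr: float = 1e-5
    epochs: int = 3000
    batch: int = 512
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        if self.pool_kernel < 1:
            raise ValueError("pooling kernel must be >= 1")
        if min(self.input_len, self.hidden_dim, self.batch, self.epochs) < 1:
            raise ValueError("dimensions and schedule must be >= 1")

    @classmethod
    def desk_scale(cls, seed=0, epochs=300, **kw) -> "EPNConfig":
        return cls(lr=1e-3, epochs=epochs, seed=seed, **kw)


@dataclass
class EPNWeights:
    """Trainable parameters: FC-1 (W, B) and the output layer (U, D)."""

    W: np.ndarray
    B: np.ndarray
    U: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        h, n = self.W.shape
        if self.B.shape != (h,) or self.U.shape != (2, h) or self.D.shape != (2,):
            raise ValueError("weight shapes are inconsistent")

    @classmethod
    def init(cls, cfg: EPNConfig, rng) -> "EPNWeights":
        def glorot(n_out, n_in):
            limit = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-limit, limit, (n_out, n_in))

        return cls(W=glorot(cfg.hidden_dim, cfg.input_len),
                   B=np.zeros(cfg.hidden_dim),
                   U=glorot(2, cfg.hidden_dim),
                   D=np.zeros(2))


def avg_pool(x, s: int) -> np.ndarray:
    """Length-preserving moving average with repeat padding of the tail.

    A(n) = mean(x[n .. n+s-1]); indices past the end read the repeated
    last sample.  Works on a vector or a batch (last axis pooled).
    """
    if s < 1:
        raise ValueError("pooling kernel must be >= 1")
    x = np.asarray(x, dtype=float)
    if s == 1:
        return x.copy()
    pad = [(0, 0)] * (x.ndim - 1) + [(0, s - 1)]
    xp = np.pad(x, pad, mode="edge")
    c = np.cumsum(xp, axis=-1, dtype=float)
    c = np.concatenate([np.zeros_like(c[..., :1]), c], axis=-1)
    return (c[..., s:] - c[..., :-s]) / s


def _forward_batch(X, w: EPNWeights, cfg: EPNConfig, rng=None, training=False):
    """Batched forward pass; returns (Z, cache) with cache for backprop."""
    A = avg_pool(X, cfg.pool_kernel)
    pre = A @ w.W.T + w.B
    H = np.maximum(pre, 0.0)
    if training and cfg.dropout_p > 0:
        keep = 1.0 - cfg.dropout_p
        mask = (rng.random(H.shape) < keep) / keep
        C = H * mask
    else:
        mask = None
        C = H
    Z = C @ w.U.T + w.D
    return Z, (A, pre, C, mask)


def forward(x, w: EPNWeights, cfg: EPNConfig, training=False, rng=None):
    """Forward pass for a single input vector; returns Z as a 2-vector.

    Dropout is active only when ``training`` is set (inverted scaling, so
    the inference-time expectation matches); inference is deterministic.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (cfg.input_len,):
        raise ValueError(f"input must have shape ({cfg.input_len},)")
    if training and rng is None:
        rng = np.random.default_rng(cfg.seed)
    Z, _ = _forward_batch(x[None, :], w, cfg, rng=rng, training=training)
    return Z[0]


def phase_from_output(Z) -> float:
    """Decode the predicted phase: the angle of Z_re + i Z_im, in (-pi, pi]."""
    Z = np.asarray(Z, dtype=float)
    re, im = Z[..., 0], Z[..., 1]
    if np.any((re == 0) & (im == 0)):
        raise ValueError("phase of the zero output vector is undefined")
    return wrap_phase(np.arctan2(im, re))


def predict_phase(X, w: EPNWeights, cfg: EPNConfig) -> np.ndarray:
    """Vectorized inference: phases for a batch of input vectors."""
    Z, _ = _forward_batch(np.atleast_2d(np.asarray(X, dtype=float)), w, cfg)
    return np.atleast_1d(phase_from_output(Z))


class _Adam:
    """Plain Adam over a list of arrays."""

    def __init__(self, params, lr, b1, b2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(train_data, val_data, cfg: EPNConfig):
    """Train the network by MSE regression onto unit phasor targets.

    Parameters
    ----------
    train_data, val_data : tuple (X, theta)
        Input matrix (n, input_len) and ground-truth phases (n,) in rad.
        ``val_data`` may be ``None`` or empty; the validation loss trace is
        then omitted.
    cfg : EPNConfig

    Returns
    -------
    (EPNWeights, dict) - final weights and per-epoch loss traces
    ``{"train": [...], "val": [...]}``.  Fully reproducible per seed.
    """
    X, theta = train_data
    X = np.asarray(X, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if X.size == 0:
        raise ValueError("empty training set")
    Y = np.column_stack([np.cos(theta), np.sin(theta)])

    has_val = val_data is not None and np.size(val_data[0]) > 0
    if has_val:
        Xv = np.asarray(val_data[0], dtype=float)
        Yv = np.column_stack([np.cos(val_data[1]), np.sin(val_data[1])])

    rng = np.random.default_rng(cfg.seed)
    w = EPNWeights.init(cfg, rng)
    opt = _Adam([w.W, w.B, w.U, w.D], cfg.lr, cfg.adam_beta1, cfg.adam_beta2,
                cfg.adam_eps)
    n = X.shape[0]
    trace = {"train": [], "val": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch):
            idx = order[lo:lo + cfg.batch]
            Xb, Yb = X[idx], Y[idx]
            Z, (A, pre, C, mask) = _forward_batch(Xb, w, cfg, rng=rng,
                                                  training=True)
            err = Z - Yb
            loss = float(np.mean(err ** 2))
            epoch_loss += loss * len(idx)
            dZ = 2.0 * err / err.size
            dU = dZ.T @ C
            dD = dZ.sum(axis=0)
            dC = dZ @ w.U
            dH = dC if mask is None else dC * mask
            dpre = dH * (pre > 0)
            dW = dpre.T @ A
            dB = dpre.sum(axis=0)
            opt.step([w.W, w.B, w.U, w.D], [dW, dB, dU, dD])
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        trace["train"].append(epoch_loss)
        if has_val:
            Zv, _ = _forward_batch(Xv, w, cfg)
            trace["val"].append(float(np.mean((Zv - Yv) ** 2)))
    return w, trace


def save_weights(w: EPNWeights, path, cfg: EPNConfig = None) -> None:
    """Serialize weights (and optionally the config) to an .npz archive."""
    meta = json.dumps(asdict(cfg)) if cfg is not None else "{}"
    np.savez(Path(path), W=w.W, B=w.B, U=w.U, D=w.D,
             meta=np.array(meta))


def load_weights(path):
    """Load weights saved by :func:`save_weights`; returns (weights, cfg)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            w = EPNWeights(W=z["W"], B=z["B"], U=z["U"], D=z["D"])
            meta = json.loads(str(z["meta"]))
    except (zipfile.BadZipFile, KeyError, ValueError) as exc:
        raise ValueError(f"corrupt weight file {path}: {exc}") from exc
    cfg = EPNConfig(**meta) if meta else None
    return w, cfg
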