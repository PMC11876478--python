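"""Comparator phase predictors: AR forward extension, ETP peak
interpolation, and the MLOF gated network.

All three estimate the instantaneous mu-rhythm phase at "time 0" from
causal data only, each working around causal-filter edge distortion in its
own way:

* **AR** - band-filter a 1-s window, discard the distorted tail, fit an
  autoregressive model by Yule-Walker and iterate it forward (noise-free)
  to replace the tail and extend past time 0, then read the Hilbert phase.
* **ETP** - learn the subject's individual rhythm frequency (IAF) and a
  phase bias from resting data; at run time, interpolate the phase linearly
  from the last causally detected rhythm peak at the IAF cycle.
* **MLOF** - two linear branches: one proposes K complex (phasor)
  candidates, the other produces softmax gates over them; the output is
  the gated convex combination.  Trained like the EPN (MSE on the unit
  phasor, Adam).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import yule_walker

from . import io_preprocess as iop
from ._utils import wrap_phase
from .epn import _Adam
from .simulate import fit_aperiodic

__all__ = [
    "ARConfig", "ARFit", "ar_fit", "ar_predict_phase", "ar_phase_from_raw",
    "ETPState", "etp_learn", "etp_predict_phase",
    "MLOFConfig", "MLOFWeights", "mlof_forward", "mlof_predict_phase",
    "mlof_train", "save_mlof", "load_mlof",
]


# --------------------------------------------------------------------------
# AR
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ARConfig:
    """AR comparator settings: model order, window, and inner causal filter.

    The inner two-pass FIR is deliberately short (order 64): a long filter
    would distort - and force the discard of - too much of the 1-s window.
    """

    order: int = 30
    window_s: float = 1.0
    inner_filter_taps: int = 64
    band: tuple = (8.0, 13.0)
    extend_s: float = 0.256

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("AR order must be >= 1")


@dataclass(frozen=True)
class ARFit:
    """Yule-Walker solution: coefficients a_1..a_p and residual variance."""

    a: np.ndarray
    noise_var: float

    @property
    def order(self) -> int:
        return len(self.a)


def ar_fit(x, p: int) -> ARFit:
    """Fit an AR(p) model by the Yule-Walker method (biased autocorrelation).

    ``x`` is expected to be the band-filtered window segment with the
    edge-distorted samples already removed.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * p:
        raise ValueError(f"segment of {x.size} samples too short for order {p}")
    if not np.any(x):
        raise ValueError("degenerate input: all-zero segment")
    try:
        rho, sigma = yule_walker(x, order=p, method="mle", demean=False)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate input: singular autocorrelation ({exc})")
    if not np.all(np.isfinite(rho)):
        raise ValueError("degenerate input: non-finite Yule-Walker solution")
    return ARFit(a=rho, noise_var=float(sigma ** 2))


def ar_extend(fit: ARFit, x, n_ahead: int) -> np.ndarray:
    """Iterate X_t = sum a_i X_{t-i} forward (noise term zero)."""
    x = np.asarray(x, dtype=float)
    p = fit.order
    buf = np.concatenate([x[-p:], np.zeros(n_ahead)])
    rms = np.sqrt(np.mean(x ** 2))
    a_rev = fit.a[::-1]
    for i in range(n_ahead):
        buf[p + i] = buf[i:p + i] @ a_rev
        if abs(buf[p + i]) > 1e6 * max(rms, 1e-30):
            raise FloatingPointError("AR forward iteration is explosive")
    return buf[p:]


def ar_predict_phase(fit: ARFit, x, extend_s: float = 0.256, rate: float = 500.0,
                     n_replace: int = 64) -> float:
    """Phase at time 0 from forward-extending the filtered segment.

    ``x`` ends ``n_replace`` samples before time 0 (the discarded,
    filter-distorted tail); the AR model regenerates that tail and another
    ``extend_s`` seconds beyond it, the Hilbert phase of the concatenation
    is taken, and the value at the time-0 sample is returned.
    """
    x = np.asarray(x, dtype=float)
    n_ahead = n_replace + int(round(extend_s * rate))
    ext = ar_extend(fit, x, n_ahead)
    full = np.concatenate([x, ext])
    idx_time0 = x.size + n_replace - 1
    return float(iop.hilbert_phase(full)[idx_time0])


def ar_phase_from_raw(raw_window, cfg: ARConfig = ARConfig(),
                      rate: float = 500.0) -> float:
    """Full AR chain from a raw 1-s window whose last sample is time 0."""
    raw_window = np.asarray(raw_window, dtype=float)
    expected = int(round(cfg.window_s * rate))
    if raw_window.size != expected:
        raise ValueError(f"AR expects {expected} raw samples, got {raw_window.size}")
    b = iop.design_bandpass(cfg.band[0], cfg.band[1], cfg.inner_filter_taps, rate)
    filt = sps.filtfilt(b, [1.0], raw_window, padtype="even", padlen=len(b) - 1)
    discard = cfg.inner_filter_taps
    kept = filt[:-discard]
    fit = ar_fit(kept, cfg.order)
    return ar_predict_phase(fit, kept, cfg.extend_s, rate, n_replace=discard)


# --------------------------------------------------------------------------
# ETP
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ETPState:
    """Learned ETP parameters: IAF, its cycle in ms, and the phase bias."""

    iaf: float
    t_adj_ms: float
    phase_bias: float
    filter_taps: int = 129

    def __post_init__(self):
        if self.t_adj_ms <= 0:
            raise ValueError("rhythm cycle must be positive")

    def target_offset_ms(self, theta_target: float) -> float:
        """Time to add to the last peak to reach a target phase (Eq. form
        T* = theta x T_adj / 2 pi)."""
        return theta_target * self.t_adj_ms / (2.0 * np.pi)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "ETPState":
        return cls(**json.loads(Path(path).read_text()))


def _causal_bandpass(x, band, taps, rate):
    b = sps.firwin(taps if taps % 2 else taps + 1, band, pass_zero=False,
                   window="hamming", fs=rate)
    return sps.lfilter(b, [1.0], x), (len(b) - 1) // 2


def _detect_peaks(filt, iaf, rate):
    distance = max(1, int(round(0.5 * rate / iaf)))
    peaks, _ = sps.find_peaks(filt, distance=distance, prominence=1e-12)
    return peaks


def estimate_iaf(x, rate, band=(8.0, 13.0)) -> float:
    """Individual rhythm frequency: interpolated Welch-PSD peak in band.

    Raises if no peak in the band rises above twice the aperiodic trend.
    """
    x = np.asarray(x, dtype=float)
    nperseg = min(int(round(10 * rate)), x.size)
    freqs, psd = sps.welch(x, fs=rate, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
    sel = (freqs >= 2) & (freqs <= 45) & (psd > 0)
    trend = fit_aperiodic(freqs[sel], psd[sel]).psd(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    idx = np.flatnonzero(in_band)
    k = idx[np.argmax(psd[idx])]
    if psd[k] < 2.0 * trend[k]:
        raise ValueError("no rhythm: band peak does not rise above the "
                         "aperiodic trend")
    # parabolic interpolation on log-power around the peak bin
    if 0 < k < len(freqs) - 1:
        y = np.log10(psd[k - 1:k + 2])
        denom = y[0] - 2 * y[1] + y[2]
        delta = 0.5 * (y[0] - y[2]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(freqs[k] + delta * (freqs[1] - freqs[0]))


def _etp_raw_phase(filt_peaks, delay, t_eval, iaf, rate):
    """Uncorrected interpolated phase at sample index ``t_eval``.

    ``filt_peaks`` are peak indices in the causally filtered series; a peak
    is usable once observed (index <= t_eval) and its position in raw time
    is compensated by the filter group delay.
    """
    usable = filt_peaks[filt_peaks <= t_eval]
    if usable.size == 0:
        raise ValueError("no rhythm peak detected in the causal history")
    last = usable[-1] - delay
    dt = (t_eval - last) / rate
    return wrap_phase(2.0 * np.pi * iaf * dt)


def etp_learn(resting, rate=1000.0, band=(8.0, 13.0), ground_truth_phase=None,
              filter_taps=129, eval_step_s=0.1, min_duration_s=180.0) -> ETPState:
    """Learn the IAF cycle and phase bias from resting data.

    The bias is the 1-degree-grid offset minimizing the mean absolute
    circular error between the causally interpolated phase and
    ``ground_truth_phase`` (per-sample radians aligned with ``resting``)
    over evaluation points every ``eval_step_s``; ties break toward zero.
    """
    resting = np.asarray(resting, dtype=float)
    if resting.size < min_duration_s * rate:
        raise ValueError(f"need at least {min_duration_s:g} s of resting data")
    iaf = estimate_iaf(resting, rate, band)
    t_adj_ms = 1000.0 / iaf

    phase_bias = 0.0
    if ground_truth_phase is not None:
        truth = np.asarray(ground_truth_phase, dtype=float)
        filt, delay = _causal_bandpass(resting, band, filter_taps, rate)
        peaks = _detect_peaks(filt, iaf, rate)
        step = max(1, int(round(eval_step_s * rate)))
        t_grid = np.arange(int(2 * rate), resting.size, step)
        raw_pred = []
        t_used = []
        for t in t_grid:
            try:
                raw_pred.append(_etp_raw_phase(peaks, delay, t, iaf, rate))
                t_used.append(t)
            except ValueError:
                continue
        if raw_pred:
            raw_pred = np.asarray(raw_pred)
            truth_at = truth[np.asarray(t_used)]
            grid = np.radians(np.arange(-180, 180))
            # sweep ordered by |bias| so exact ties resolve toward zero
            order = np.argsort(np.abs(grid), kind="stable")
            best = (np.inf, 0.0)
            for g in grid[order]:
                mace = np.mean(np.abs(wrap_phase(raw_pred + g - truth_at)))
                if mace < best[0]:
                    best = (mace, float(g))
            phase_bias = best[1]
    return ETPState(iaf=iaf, t_adj_ms=t_adj_ms, phase_bias=phase_bias,
                    filter_taps=filter_taps)


def etp_predict_phase(history, state: ETPState, rate=1000.0,
                      band=(8.0, 13.0)) -> float:
    """Phase at time 0 (the sample right after ``history``) by interpolation
    from the last causally detected rhythm peak at the learned IAF cycle."""
    history = np.asarray(history, dtype=float)
    filt, delay = _causal_bandpass(history, band, state.filter_taps, rate)
    peaks = _detect_peaks(filt, state.iaf, rate)
    if peaks.size == 0:
        raise ValueError("no rhythm peak detected in the causal history")
    raw = _etp_raw_phase(peaks, delay, history.size, state.iaf, rate)
    return float(wrap_phase(raw + state.phase_bias))


# --------------------------------------------------------------------------
# MLOF
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MLOFConfig:
    """Gated multi-bank phasor network settings."""

    n_banks: int = 8
    input_len: int = 250
    lr: float = 1e-5
    epochs: int = 3000
    batch: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.n_banks < 1:
            raise ValueError("need at least one frequency bank")

    @classmethod
    def desk_scale(cls, seed=0, epochs=300, **kw) -> "MLOFConfig":
        return cls(lr=1e-3, epochs=epochs, seed=seed, **kw)


@dataclass
class MLOFWeights:
    """Candidate branch (Wa, ba) and gating branch (Wb, bb)."""

    Wa: np.ndarray  # (2K, input_len)
    ba: np.ndarray  # (2K,)
    Wb: np.ndarray  # (K, input_len)
    bb: np.ndarray  # (K,)

    @classmethod
    def init(cls, cfg: MLOFConfig, rng) -> "MLOFWeights":
        def glorot(n_out, n_in):
            limit = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-limit, limit, (n_out, n_in))

        k = cfg.n_banks
        return cls(Wa=glorot(2 * k, cfg.input_len), ba=np.zeros(2 * k),
                   Wb=glorot(k, cfg.input_len), bb=np.zeros(k))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _mlof_forward_batch(X, w: MLOFWeights, cfg: MLOFConfig):
    n = X.shape[0]
    cand = (X @ w.Wa.T + w.ba).reshape(n, cfg.n_banks, 2)
    gates = _softmax(X @ w.Wb.T + w.bb)
    Z = np.einsum("nk,nkc->nc", gates, cand)
    return Z, cand, gates


def mlof_forward(x, w: MLOFWeights, cfg: MLOFConfig):
    """Single forward pass; returns (Z, gates).

    Branch A proposes K phasor candidates, branch B softmax gates; Z is the
    gated convex combination, so it always lies in the candidates' hull.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (cfg.input_len,):
        raise ValueError(f"input must have shape ({cfg.input_len},)")
    Z, _, gates = _mlof_forward_batch(x[None, :], w, cfg)
    return Z[0], gates[0]


def mlof_predict_phase(X, w: MLOFWeights, cfg: MLOFConfig) -> np.ndarray:
    from .epn import phase_from_output

    Z, _, _ = _mlof_forward_batch(np.atleast_2d(np.asarray(X, dtype=float)),
                                  w, cfg)
    return np.atleast_1d(phase_from_output(Z))


def mlof_train(train_data, val_data, cfg: MLOFConfig):
    """Train MLOF exactly like the EPN: Adam on MSE to unit phasor targets."""
    X, theta = train_data
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty training set")
    Y = np.column_stack([np.cos(theta), np.sin(theta)])
    has_val = val_data is not None and np.size(val_data[0]) > 0
    if has_val:
        Xv = np.asarray(val_data[0], dtype=float)
        Yv = np.column_stack([np.cos(val_data[1]), np.sin(val_data[1])])

    rng = np.random.default_rng(cfg.seed)
    w = MLOFWeights.init(cfg, rng)
    opt = _Adam([w.Wa, w.ba, w.Wb, w.bb], cfg.lr, 0.9, 0.999, 1e-8)
    n = X.shape[0]
    trace = {"train": [], "val": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch):
            idx = order[lo:lo + cfg.batch]
            Xb, Yb = X[idx], Y[idx]
            Z, cand, gates = _mlof_forward_batch(Xb, w, cfg)
            err = Z - Yb
            loss = float(np.mean(err ** 2))
            epoch_loss += loss * len(idx)
            dZ = 2.0 * err / err.size                       # (n, 2)
            dcand = gates[:, :, None] * dZ[:, None, :]      # (n, K, 2)
            dG = np.einsum("nkc,nc->nk", cand, dZ)          # (n, K)
            dlogits = gates * (dG - (dG * gates).sum(axis=1, keepdims=True))
            dWa = dcand.reshape(len(idx), -1).T @ Xb
            dba = dcand.reshape(len(idx), -1).sum(axis=0)
            dWb = dlogits.T @ Xb
            dbb = dlogits.sum(axis=0)
            opt.step([w.Wa, w.ba, w.Wb, w.bb], [dWa, dba, dWb, dbb])
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        trace["train"].append(epoch_loss)
        if has_val:
            Zv, _, _ = _mlof_forward_batch(Xv, w, cfg)
            trace["val"].append(float(np.mean((Zv - Yv) ** 2)))
    return w, trace


def save_mlof(w: MLOFWeights, path, cfg: MLOFConfig = None) -> None:
    meta = json.dumps(asdict(cfg)) if cfg is not None else "{}"
    np.savez(Path(path), Wa=w.Wa, ba=w.ba, Wb=w.Wb, bb=w.bb,
             meta=np.array(meta))


def load_mlof(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as z:
        w = MLOFWeights(Wa=z["Wa"], ba=z["ba"], Wb=z["Wb"], bb=z["bb"])
        meta = json.loads(str(z["meta"]))
    cfg = MLOFConfig(**meta) if meta else None
    return w, cfg
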