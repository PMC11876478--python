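"""Dataset construction: splits, overlapping epochs, labels, model inputs.

Every training/testing example is a 6.16 s epoch of 3080 samples whose
center sample (0-based index 1540) is "time 0" - the instant a stimulation
trigger would fire.  The ground-truth phase is the Hilbert angle of the
zero-phase bandpassed epoch read at that center, which by construction lies
inside the region the two-pass filter leaves undistorted.  Model inputs are
strictly causal slices ending at time 0:

* EPN / MLOF: the 250 first-order differences of the 251 raw samples from
  -0.5 s to 0 s (500 Hz);
* AR: the 500 raw samples from -1.0 s to 0 s (500 Hz);
* ETP: the causal history, i.e. the first half of the window (1000 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io_preprocess as iop

__all__ = [
    "WINDOW_LEN",
    "CENTER_INDEX",
    "OVERLAP_SCHEDULE",
    "TrialWindow",
    "DatasetSplit",
    "split_resting",
    "segment",
    "label_phase",
    "build_model_inputs",
    "build_dataset",
]

#: Epoch length in samples (6.16 s at 500 Hz; 3.08 s at 1000 Hz).
WINDOW_LEN = 3080
#: 0-based index of "time 0", the first sample of the second half.
CENTER_INDEX = 1540
#: Overlap augmentation schedule in samples (0 s to 1.28 s at 500 Hz).
OVERLAP_SCHEDULE = (0, 64, 128, 192, 256, 320, 384, 448, 512, 576, 640)

#: Samples of causal history each model consumes (ending at time 0).
INPUT_SPANS = {"epn": 251, "mlof": 251, "ar": 500, "etp": CENTER_INDEX}


@dataclass
class TrialWindow:
    """One fixed-length epoch with its ground-truth phase at the center."""

    raw: np.ndarray
    theta_true: float = np.nan
    subject_id: str = ""
    start_index: int = -1  # position of raw[0] in the source signal
    center_index: int = CENTER_INDEX

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.size != WINDOW_LEN:
            raise ValueError(f"trial window must hold {WINDOW_LEN} samples")
        if self.center_index != CENTER_INDEX:
            raise ValueError(f"center index must be {CENTER_INDEX}")


@dataclass
class DatasetSplit:
    """Chronologically disjoint train/test sample ranges of one recording."""

    train_range: tuple
    test_range: tuple
    overlap_schedule: tuple = OVERLAP_SCHEDULE
    train: list = field(default_factory=list)
    test: list = field(default_factory=list)


def split_resting(x, rate, train_s=240.0, test_s=60.0) -> DatasetSplit:
    """Split a resting signal into leading train and trailing test ranges."""
    x = np.asarray(x)
    need = int(round((train_s + test_s) * rate))
    if x.size < need:
        raise ValueError(
            f"recording of {x.size / rate:.1f} s cannot cover "
            f"{train_s:g} + {test_s:g} s")
    n_train = int(round(train_s * rate))
    return DatasetSplit(train_range=(0, n_train), test_range=(n_train, need))


def segment(x, window_len=WINDOW_LEN, overlap=0, subject_id="",
            offset=0) -> list:
    """Tile a signal into full-length windows with a fixed overlap.

    Windows start every ``window_len - overlap`` samples; only complete
    windows are returned.  ``offset`` shifts recorded start indices so that
    windows cut from a sub-range keep coordinates of the parent signal.
    """
    x = np.asarray(x, dtype=float)
    if not 0 <= overlap < window_len:
        raise ValueError("overlap must satisfy 0 <= overlap < window length")
    stride = window_len - overlap
    out = []
    for start in range(0, x.size - window_len + 1, stride):
        out.append(TrialWindow(raw=x[start:start + window_len],
                               subject_id=subject_id,
                               start_index=start + offset))
    return out


def pooled_segments(x, schedule=OVERLAP_SCHEDULE, subject_id="",
                    offset=0) -> list:
    """Windows pooled over an overlap schedule, deduplicated by start index."""
    seen = {}
    for ov in schedule:
        for w in segment(x, overlap=ov, subject_id=subject_id, offset=offset):
            seen.setdefault(w.start_index, w)
    return [seen[s] for s in sorted(seen)]


def label_phase(w: TrialWindow, band=(8.0, 13.0), taps=769,
                rate=500.0) -> float:
    """Ground-truth phase: zero-phase bandpass + Hilbert, read at the center.

    The center lies a half-window away from either edge, inside the region
    the two-pass filter leaves unaffected, so the label is free of causal
    edge distortion.
    """
    filt = iop.zero_phase_bandpass(w.raw, band[0], band[1], taps, rate)
    theta = float(iop.hilbert_phase(filt)[w.center_index])
    w.theta_true = theta
    return theta


def build_model_inputs(w: TrialWindow, kind: str, rate: float) -> np.ndarray:
    """Causal input vector for one model; never reads past the center."""
    kind = kind.lower()
    if kind not in INPUT_SPANS:
        raise ValueError(f"unknown model kind {kind!r}")
    if kind in ("epn", "mlof", "ar") and rate != 500:
        raise ValueError(f"{kind} operates on 500 Hz data, got {rate} Hz")
    if kind == "etp" and rate != 1000:
        raise ValueError(f"etp operates on 1000 Hz data, got {rate} Hz")
    c = w.center_index
    if kind in ("epn", "mlof"):
        seg = w.raw[c - 250:c + 1]           # 251 raw samples, -0.5 s .. 0 s
        return iop.backward_difference(seg)  # 250 differences
    if kind == "ar":
        return w.raw[c - 499:c + 1].copy()   # 500 raw samples, -1.0 s .. 0 s
    return w.raw[:c].copy()                  # etp: full causal first half


def build_dataset(signal, rate, kind="epn", train_s=240.0, test_s=60.0,
                  schedule=OVERLAP_SCHEDULE, subject_id="",
                  true_phase=None, band=(8.0, 13.0), taps=769,
                  val_fraction=0.1):
    """Windows + labels + model inputs for one subject's resting signal.

    When ``true_phase`` (per-sample radians, e.g. from the simulator) is
    given, labels are read from it at each window center - the "real truth"
    mode used with synthetic data.  Otherwise labels come from the
    non-causal filter + Hilbert chain (:func:`label_phase`).

    Returns a dict with keys ``train``, ``val``, ``test``, each holding
    ``(X, theta, windows)``; train/val is a 90/10 chronological split of
    the training range.
    """
    split = split_resting(signal, rate, train_s, test_s)
    t0, t1 = split.train_range
    s0, s1 = split.test_range
    sig = np.asarray(signal, dtype=float)

    def make(lo, hi):
        wins = pooled_segments(sig[lo:hi], schedule, subject_id, offset=lo)
        for w in wins:
            if true_phase is not None:
                w.theta_true = float(true_phase[w.start_index + w.center_index])
            else:
                label_phase(w, band=band, taps=taps, rate=rate)
        X = np.stack([build_model_inputs(w, kind, rate) for w in wins])
        theta = np.array([w.theta_true for w in wins])
        return X, theta, wins

    X_tr, th_tr, w_tr = make(t0, t1)
    X_te, th_te, w_te = make(s0, s1)
    n_val = max(1, int(round(val_fraction * len(w_tr)))) if len(w_tr) > 1 else 0
    n_fit = len(w_tr) - n_val
    out = {
        "train": (X_tr[:n_fit], th_tr[:n_fit], w_tr[:n_fit]),
        "val": (X_tr[n_fit:], th_tr[n_fit:], w_tr[n_fit:]),
        "test": (X_te, th_te, w_te),
        "split": split,
    }
    return out
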