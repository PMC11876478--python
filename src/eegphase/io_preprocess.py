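"""EEG file reading and the preprocessing primitives of the prediction chain.

The offline chain is: read a multichannel recording, spatially sharpen the
local sensorimotor rhythm with a 5-point Hjorth (surface-Laplacian)
transform, resample to the working rate, and - for ground-truth labeling
only - apply a two-pass zero-phase FIR bandpass followed by the Hilbert
transform.  The first-order difference y(n) = x(n+1) - x(n) removes slow
electrode drift before samples reach the learned predictors.

Amplitudes are kept in microvolts end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.signal import hilbert as _hilbert

from ._utils import wrap_phase

__all__ = [
    "EEGRecording",
    "MontageSpec",
    "read_recording",
    "hjorth_laplacian",
    "backward_difference",
    "resample",
    "zero_phase_bandpass",
    "hilbert_phase",
    "save_signal",
    "load_signal",
]


@dataclass
class EEGRecording:
    """Multichannel EEG time series.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel amplitudes in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered, unique channel names (10-20 system).
    """

    samples: np.ndarray
    rate: float
    channel_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise LookupError("duplicate channel labels in recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise LookupError(f"channel {label!r} not in recording") from None
        return self.samples[idx]


@dataclass(frozen=True)
class MontageSpec:
    """Center electrode plus its four Hjorth neighbors."""

    center: str
    neighbors: tuple

    def __post_init__(self):
        if len(self.neighbors) != 4:
            raise ValueError("Hjorth montage needs exactly four neighbors")
        if self.center in self.neighbors:
            raise ValueError("center electrode cannot be its own neighbor")


#: The C4-centered montage used for right-sensorimotor mu recordings.
C4_MONTAGE = MontageSpec(center="C4", neighbors=("FC2", "FC6", "CP2", "CP6"))
#: Mirror montage over the left sensorimotor cortex.
C3_MONTAGE = MontageSpec(center="C3", neighbors=("FC1", "FC5", "CP1", "CP5"))


def read_recording(path, fmt=None) -> EEGRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording via MNE.

    Parameters
    ----------
    path : str or Path
        Header file (.vhdr) or EDF file.
    fmt : {"brainvision", "edf"}, optional
        Inferred from the suffix when omitted.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"vhdr": "brainvision", "edf": "edf"}.get(suffix.lstrip("."))
        if fmt is None:
            raise ValueError(f"cannot infer EEG format from suffix {suffix!r}")
    try:
        if fmt == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # unreadable / inconsistent header
        raise ValueError(f"could not parse {fmt} file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(samples=data, rate=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names))


def hjorth_laplacian(rec: EEGRecording, montage: MontageSpec) -> np.ndarray:
    """5-point sum-difference Hjorth transform: center minus neighbor mean.

    A discrete surface Laplacian that suppresses activity common to the
    patch and sharpens the local rhythm under the center electrode.
    """
    center = rec.channel(montage.center)
    neigh = np.stack([rec.channel(c) for c in montage.neighbors])
    return center - neigh.mean(axis=0)


def backward_difference(x) -> np.ndarray:
    """First-order difference y(n) = x(n+1) - x(n); output one sample shorter."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to difference")
    return np.diff(x)


def resample(x, from_rate, to_rate) -> np.ndarray:
    """Anti-aliased rational-rate conversion (polyphase, Kaiser window)."""
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("rates must be positive")
    x = np.asarray(x, dtype=float)
    if from_rate == to_rate:
        return x.copy()
    from fractions import Fraction

    frac = Fraction(to_rate / from_rate).limit_denominator(10000)
    return sps.resample_poly(x, frac.numerator, frac.denominator,
                             window=("kaiser", 5.0))


def design_bandpass(low, high, taps, rate) -> np.ndarray:
    """Linear-phase FIR bandpass (windowed sinc, Hamming)."""
    if not (0 < low < high < rate / 2):
        raise ValueError("band edges must satisfy 0 < low < high < rate/2")
    if taps < 3:
        raise ValueError("need at least 3 taps")
    if taps % 2 == 0:
        taps += 1  # type-I FIR needed for a bandpass
    return sps.firwin(taps, [low, high], pass_zero=False, window="hamming", fs=rate)


def zero_phase_bandpass(x, low=8.0, high=13.0, taps=769, rate=500.0) -> np.ndarray:
    """Two-pass (forward-backward) zero-phase FIR bandpass.

    Symmetric edge padding of one filter length per side keeps the central
    region undistorted; samples within roughly one filter length of either
    edge remain unreliable and callers must not read phase there.
    """
    x = np.asarray(x, dtype=float)
    b = design_bandpass(low, high, taps, rate)
    if x.size <= 3 * len(b):
        raise ValueError(
            f"signal of {x.size} samples too short for two-pass filtering "
            f"with {len(b)} taps")
    return sps.filtfilt(b, [1.0], x, padtype="even", padlen=len(b))


def hilbert_phase(x) -> np.ndarray:
    """Instantaneous phase (rad) of the analytic signal, in (-pi, pi].

    Convention: for cos(wt) the phase at a signal maximum is 0.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if not np.any(x):
        raise ValueError("phase of the all-zero signal is undefined")
    return wrap_phase(np.angle(_hilbert(x)))


def save_signal(path, x, rate, channel=None, provenance=None) -> None:
    """Write a single-channel signal as .npy with a JSON sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(x, dtype=float))
    meta = {"rate": float(rate), "channel": channel, "provenance": provenance}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_signal(path):
    """Read a signal written by :func:`save_signal`; returns (x, meta)."""
    path = Path(path)
    x = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return x, meta
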