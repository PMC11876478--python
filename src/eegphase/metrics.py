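"""Circular error statistics, band SNR estimation and model comparison.

The five summary statistics follow the closed-loop phase-prediction
literature: for signed wrapped errors ``d_i = wrap(theta_pred - theta_true)``
with mean resultant ``R = |1/N sum exp(i d_i)|``,

* MEAN  = Arg(1/N sum exp(i d_i))          (circular mean error, rad)
* VAR   = 1 - R                            (circular variance, [0, 1])
* SD    = sqrt(-2 log(1 - VAR))            (circular standard deviation, rad)
* MACE  = mean |d_i|                       (mean absolute circular error, rad)
* ACC   = 1 - mean(|d_i| in degrees) / 180 = 1 - MACE / pi

ACC is defined through MACE: the two are redundant by construction
(``acc == 1 - mace/pi`` exactly), which is the only reading that makes the
published accuracy/MACE pairs of this model family mutually consistent.

SNR is a band-power ratio: average Welch PSD over the mu band (8-13 Hz)
divided by the average PSD over a broad band (2-45 Hz), so white noise
calibrates to an SNR of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal, stats

from ._utils import circ_dist

__all__ = [
    "CircularErrorSummary",
    "SNREstimate",
    "summarize_errors",
    "estimate_snr",
    "regress_accuracy_on_snr",
    "compare_models",
]


@dataclass(frozen=True)
class CircularErrorSummary:
    """Five circular statistics of a set of signed phase errors."""

    mean: float
    var: float
    sd: float
    mace: float
    acc: float
    n: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MEAN={np.degrees(self.mean):+.2f} deg  VAR={self.var:.3f}  "
            f"SD={np.degrees(self.sd):.2f} deg  MACE={self.mace:.3f} rad  "
            f"ACC={100 * self.acc:.2f}%  (n={self.n})"
        )


@dataclass(frozen=True)
class SNREstimate:
    snr: float
    band: tuple = (8.0, 13.0)
    total_band: tuple = (2.0, 45.0)


def summarize_errors(theta_pred, theta_true) -> CircularErrorSummary:
    """Summarize signed circular errors between predicted and true phases.

    Parameters
    ----------
    theta_pred, theta_true : array-like of float
        Phases in radians; equal, non-empty lengths.

    Notes
    -----
    If the mean resultant vector is exactly zero the circular mean is
    undefined; by convention it is reported as 0 with ``var = 1`` and
    ``sd = inf``.
    """
    theta_pred = np.asarray(theta_pred, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_pred.shape != theta_true.shape:
        raise ValueError("theta_pred and theta_true must have equal lengths")
    if theta_pred.size == 0:
        raise ValueError("cannot summarize an empty error set")

    d = circ_dist(theta_pred, theta_true)
    resultant = np.mean(np.exp(1j * d))
    r = abs(resultant)
    mean = float(np.angle(resultant)) if r > 0 else 0.0
    var = 1.0 - r
    sd = float(np.sqrt(-2.0 * np.log(r))) if r > 0 else float("inf")
    mace = float(np.mean(np.abs(d)))
    acc = 1.0 - np.mean(np.degrees(np.abs(d))) / 180.0
    return CircularErrorSummary(mean=mean, var=float(var), sd=sd, mace=mace,
                                acc=float(acc), n=int(theta_pred.size))


def estimate_snr(x, rate, band=(8.0, 13.0), total_band=(2.0, 45.0)) -> SNREstimate:
    """Band-ratio SNR from a Welch PSD (1-s Hann segments, 50 % overlap)."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(rate))
    if x.size < 2 * nperseg:
        raise ValueError("signal must be at least 2 s long for Welch SNR")
    freqs, psd = signal.welch(x, fs=rate, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_total = (freqs >= total_band[0]) & (freqs <= total_band[1])
    snr = float(np.mean(psd[in_band]) / np.mean(psd[in_total]))
    return SNREstimate(snr=snr, band=tuple(band), total_band=tuple(total_band))


def regress_accuracy_on_snr(points):
    """OLS of accuracy (dependent) on SNR (independent).

    Parameters
    ----------
    points : sequence of (snr, acc) pairs, at least 3.

    Returns
    -------
    dict with ``slope``, ``intercept``, ``r2_adj``, ``p_value``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (snr, acc) pairs")
    snr, acc = pts[:, 0], pts[:, 1]
    if np.ptp(snr) == 0:
        raise ValueError("degenerate design: SNR is constant")
    model = sm.OLS(acc, sm.add_constant(snr)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r2_adj": float(model.rsquared_adj),
        "p_value": float(model.pvalues[1]),
    }


def compare_models(scores, pairs):
    """Pairwise Wilcoxon signed-rank tests with Bonferroni correction.

    Parameters
    ----------
    scores : mapping of model name -> per-subject score vector (paired).
    pairs : list of (name_a, name_b) tuples to test.

    Returns
    -------
    dict mapping pair -> Bonferroni-adjusted two-sided p-value (capped at 1).
    Identical score vectors yield p = 1 (no signal to test).
    """
    m = len(pairs)
    out = {}
    for a, b in pairs:
        xa = np.asarray(scores[a], dtype=float)
        xb = np.asarray(scores[b], dtype=float)
        if xa.shape != xb.shape:
            raise ValueError(f"scores for {a} and {b} are not paired")
        if np.allclose(xa, xb):
            out[(a, b)] = 1.0
            continue
        res = stats.wilcoxon(xa, xb, zero_method="wilcox", method="auto")
        out[(a, b)] = float(min(1.0, m * res.pvalue))
    return out
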