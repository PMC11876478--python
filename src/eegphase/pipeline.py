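"""End-to-end orchestration: offline benchmark, replayed-stream emulation,
and phase-triggered event logic.

Two phase conventions coexist deliberately:

* **internal** (everything below the reporting layer): Hilbert angle of the
  real signal, cosine peak = 0 rad, range (-pi, pi];
* **protocol** (targets, triggers, reports): rising edge 0 deg, peak
  90 deg, falling edge 180 deg, trough 270 deg - i.e. protocol = internal
  + 90 deg (mod 360).

The replayed stream emulates the closed-loop environment offline: chunks of
the recording are fed in order, each model sees only its causal history,
and a trigger fires when the predicted phase enters the tolerance window of
the target (subject to a refractory period).  The true phase at each
trigger comes from the simulator's noise-free phase (or the non-causal
filter chain for real recordings), so trigger-conditioned circular error
summaries mirror a real phase-locked stimulation session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import baselines, epn, metrics, windowing
from ._utils import circ_dist_deg, wrap_phase

__all__ = [
    "RunConfig", "TriggerEvent", "to_protocol_deg", "from_protocol_deg",
    "replay_stream", "StreamPredictor", "phase_trigger", "predict_series",
    "run_benchmark", "report_to_rows",
]

MODEL_RATES = {"epn": 500.0, "mlof": 500.0, "ar": 500.0, "etp": 1000.0}


def to_protocol_deg(theta_rad) -> np.ndarray:
    """Internal radians -> protocol degrees (rising edge 0, peak 90)."""
    return np.mod(np.degrees(theta_rad) + 90.0, 360.0)


def from_protocol_deg(deg) -> np.ndarray:
    """Protocol degrees -> internal radians in (-pi, pi]."""
    return wrap_phase(np.radians(np.asarray(deg, dtype=float) - 90.0))


@dataclass(frozen=True)
class RunConfig:
    """Benchmark settings (protocol-convention targets, in degrees)."""

    models: tuple = ("epn", "mlof", "ar", "etp")
    band: tuple = (8.0, 13.0)
    target_phases_deg: tuple = (0.0, 90.0, 180.0, 270.0)
    replications: int = 100
    tolerance_deg: float = 5.0
    refractory_s: float = 1.0
    trigger_latency_samples: int = 0
    train_s: float = 240.0
    test_s: float = 60.0
    epochs: int = 300
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.tolerance_deg <= 0 or self.replications < 1 or self.refractory_s < 0:
            raise ValueError("invalid trigger configuration")


@dataclass(frozen=True)
class TriggerEvent:
    """One emitted stimulation trigger."""

    time_index: int
    target_phase_deg: float
    predicted_phase_deg: float
    model: str


def replay_stream(x, chunk: int):
    """Yield consecutive non-overlapping chunks; concatenation == input.

    The final chunk may be shorter; it is flagged by yielding
    ``(chunk_array, is_final)``.
    """
    if chunk < 1:
        raise ValueError("chunk size must be >= 1")
    x = np.asarray(x)
    for lo in range(0, x.size, chunk):
        hi = min(lo + chunk, x.size)
        yield x[lo:hi], hi == x.size


class StreamPredictor:
    """Incremental per-sample phase predictor over a replayed stream.

    Feed chunks with :meth:`feed`; each call returns one phase estimate per
    newly arrived sample (``nan`` during warm-up).  Only already-received
    samples are ever read - the strict-causality contract of the real-time
    path.
    """

    #: causal history (samples) each model needs before predicting
    WARMUP = {"epn": 251, "mlof": 251, "ar": 500, "etp": windowing.CENTER_INDEX}

    def __init__(self, kind, model=None, cfg=None, rate=None):
        kind = kind.lower()
        if kind not in MODEL_RATES:
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        self.model = model
        self.cfg = cfg
        self.rate = rate or MODEL_RATES[kind]
        self._buf = np.empty(0)

    @property
    def n_seen(self) -> int:
        return self._buf.size

    def feed(self, chunk) -> np.ndarray:
        """Ingest a chunk; return phase estimates for its samples (rad)."""
        chunk = np.atleast_1d(np.asarray(chunk, dtype=float))
        self._buf = np.concatenate([self._buf, chunk])
        out = np.full(chunk.size, np.nan)
        need = self.WARMUP[self.kind]
        for i in range(chunk.size):
            now = self._buf.size - chunk.size + i  # index of this sample
            if now + 1 < need + 1:
                continue  # warm-up: underfilled buffer
            out[i] = self._predict_at(now)
        return out

    def _predict_at(self, now: int) -> float:
        hist = self._buf[: now + 1]
        if self.kind in ("epn", "mlof"):
            x = np.diff(hist[-251:])
            if self.kind == "epn":
                return float(epn.predict_phase(x, self.model, self.cfg)[0])
            return float(baselines.mlof_predict_phase(x, self.model, self.cfg)[0])
        if self.kind == "ar":
            return baselines.ar_phase_from_raw(hist[-500:], self.model
                                               or baselines.ARConfig(), self.rate)
        # etp: prediction for the newest sample uses the history before it
        return baselines.etp_predict_phase(hist[:-1], self.model, self.rate)


def phase_trigger(theta_deg, target_deg, tolerance_deg, last_trigger, refractory,
                  now, model="epn"):
    """Emit a trigger iff the phase is within tolerance of the target and
    the refractory period since the last trigger has elapsed."""
    if not 0 < tolerance_deg < 180:
        raise ValueError("tolerance must be in (0, 180) degrees")
    if circ_dist_deg(theta_deg, target_deg) <= tolerance_deg \
            and now - last_trigger >= refractory:
        return TriggerEvent(time_index=now, target_phase_deg=float(target_deg),
                            predicted_phase_deg=float(theta_deg), model=model)
    return None


def predict_series(x, kind, model=None, cfg=None, rate=None) -> np.ndarray:
    """Per-sample causal phase predictions over a whole segment (radians).

    Semantics are identical to streaming the segment through
    :class:`StreamPredictor` sample by sample (the learned models' input
    construction is deterministic, and the ETP causal filter obeys the
    prefix property), but computed in batch where the model allows.
    Samples before warm-up are ``nan``.
    """
    kind = kind.lower()
    x = np.asarray(x, dtype=float)
    rate = rate or MODEL_RATES[kind]
    n = x.size
    out = np.full(n, np.nan)
    warm = StreamPredictor.WARMUP[kind]
    if kind in ("epn", "mlof"):
        d = np.diff(x)
        predict = (epn.predict_phase if kind == "epn"
                   else baselines.mlof_predict_phase)
        # row-by-row so results are bit-identical to the incremental
        # stream predictor (batched BLAS changes accumulation order)
        for now in range(warm, n):
            out[now] = predict(d[now - 250:now], model, cfg)[0]
        return out
    if kind == "ar":
        acfg = model or baselines.ARConfig()
        for now in range(warm - 1, n):
            out[now] = baselines.ar_phase_from_raw(x[now - 499: now + 1],
                                                   acfg, rate)
        return out
    # etp: causal filter once, peaks once, interpolate per sample
    filt, delay = baselines._causal_bandpass(x, (8.0, 13.0),
                                             model.filter_taps, rate)
    peaks = baselines._detect_peaks(filt, model.iaf, rate)
    for now in range(warm, n):
        # a peak at index j is confirmed once sample j+1 is in the history
        # (which ends at now-1), matching the incremental predictor exactly
        usable = peaks[peaks + 2 <= now]
        if usable.size == 0:
            continue
        last = usable[-1] - delay
        dt = (now - last) / rate
        out[now] = wrap_phase(2 * np.pi * model.iaf * dt + model.phase_bias)
    return out


def _train_models(subject, cfg: RunConfig, rng):
    """Per-subject training of every requested model on the 4-min range.

    ``subject`` is a SimulatedRecording at 1000 Hz; learned models are
    trained against the simulator's true phase (the "real truth" mode).
    """
    trained = {}
    datasets = {}
    rec500 = subject.resample_to(500.0)
    for kind in cfg.models:
        if kind in ("epn", "mlof"):
            ds = windowing.build_dataset(
                rec500.signal, 500.0, kind=kind, train_s=cfg.train_s,
                test_s=cfg.test_s, true_phase=rec500.true_phase)
            datasets[kind] = ds
            seed = int(rng.integers(0, 2 ** 31 - 1))
            if kind == "epn":
                mcfg = epn.EPNConfig(lr=cfg.lr, epochs=cfg.epochs, seed=seed)
                w, _ = epn.train(ds["train"][:2], ds["val"][:2], mcfg)
            else:
                mcfg = baselines.MLOFConfig(lr=cfg.lr, epochs=cfg.epochs,
                                            seed=seed)
                w, _ = baselines.mlof_train(ds["train"][:2], ds["val"][:2], mcfg)
            trained[kind] = (w, mcfg)
        elif kind == "ar":
            ds = windowing.build_dataset(
                rec500.signal, 500.0, kind="ar", train_s=cfg.train_s,
                test_s=cfg.test_s, true_phase=rec500.true_phase)
            datasets[kind] = ds
            trained[kind] = (baselines.ARConfig(band=cfg.band), None)
        elif kind == "etp":
            n_train = int(cfg.train_s * subject.rate)
            state = baselines.etp_learn(
                subject.signal[:n_train], rate=subject.rate, band=cfg.band,
                ground_truth_phase=subject.true_phase[:n_train],
                min_duration_s=min(180.0, cfg.train_s))
            ds = windowing.build_dataset(
                subject.signal, 1000.0, kind="etp", train_s=cfg.train_s,
                test_s=cfg.test_s, true_phase=subject.true_phase)
            datasets[kind] = ds
            trained[kind] = (state, None)
    return trained, datasets, rec500


def _window_predictions(kind, model, mcfg, ds):
    X, theta_true, wins = ds["test"]
    if kind == "epn":
        pred = epn.predict_phase(X, model, mcfg)
    elif kind == "mlof":
        pred = baselines.mlof_predict_phase(X, model, mcfg)
    elif kind == "ar":
        pred = np.array([baselines.ar_phase_from_raw(x, model, 500.0)
                         for x in X])
    else:
        # each ETP input is already the causal history ending just before
        # the labeled center sample
        pred = np.array([baselines.etp_predict_phase(x, model, 1000.0)
                         for x in X])
    return pred, theta_true


def run_benchmark(subjects, cfg: RunConfig = RunConfig(),
                  evaluation: str = "windows"):
    """Benchmark all configured models on a cohort of synthetic subjects.

    Parameters
    ----------
    subjects : list of SimulatedRecording (native 1000 Hz)
    cfg : RunConfig
    evaluation : {"windows", "triggers"}
        "windows": score predictions at test-epoch centers against the true
        phase (fast, the offline benchmark).  "triggers": replay the test
        minute as a stream, emit phase triggers per target phase, and score
        the prediction at each trigger instant - the real-time emulation.

    Returns
    -------
    dict with per-subject/model circular error summaries, SNRs, pairwise
    Wilcoxon comparisons of accuracy, and (given >= 3 subjects) the
    accuracy~SNR regression per model.
    """
    if evaluation not in ("windows", "triggers"):
        raise ValueError("evaluation must be 'windows' or 'triggers'")
    rng = np.random.default_rng(cfg.seed)
    summaries = []
    acc_table = {m: [] for m in cfg.models}
    snrs = []
    for si, subject in enumerate(subjects):
        trained, datasets, rec500 = _train_models(subject, cfg, rng)
        n_train_500 = int(cfg.train_s * 500)
        test_sig_500 = rec500.signal[n_train_500:]
        snr = metrics.estimate_snr(test_sig_500, 500.0).snr
        snrs.append(snr)
        # session order is shuffled (protocol detail; results are per-model)
        session_order = list(cfg.models)
        rng.shuffle(session_order)
        for kind in session_order:
            model, mcfg = trained[kind]
            if evaluation == "windows":
                pred, true = _window_predictions(kind, model, mcfg,
                                                 datasets[kind])
                summ = metrics.summarize_errors(pred, true)
                summaries.append({"subject": si, "model": kind, "phase": "all",
                                  "snr": snr, **_summ_dict(summ)})
                acc_table[kind].append(summ.acc)
            else:
                rows = _trigger_sessions(subject, rec500, kind, model, mcfg,
                                         cfg, si, snr)
                summaries.extend(rows)
                pooled = [r for r in rows if r["phase"] == "all"]
                if pooled:
                    acc_table[kind].append(pooled[0]["acc"])
    report = {"summaries": summaries, "snr": snrs, "acc": acc_table,
              "evaluation": evaluation}
    if len(subjects) >= 3:
        report["regression"] = {
            m: metrics.regress_accuracy_on_snr(list(zip(snrs, acc_table[m])))
            for m in cfg.models if len(acc_table[m]) == len(snrs)}
    if len(subjects) >= 2 and len(cfg.models) >= 2:
        pairs = [(a, b) for i, a in enumerate(cfg.models)
                 for b in cfg.models[i + 1:]]
        report["comparisons"] = metrics.compare_models(acc_table, pairs)
    return report


def _summ_dict(s: metrics.CircularErrorSummary) -> dict:
    return {"mean": s.mean, "var": s.var, "sd": s.sd, "mace": s.mace,
            "acc": s.acc, "n": s.n}


def _trigger_sessions(subject, rec500, kind, model, mcfg, cfg: RunConfig,
                      si, snr):
    rate = MODEL_RATES[kind]
    rec = subject if rate == 1000.0 else rec500
    n_train = int(cfg.train_s * rate)
    sig = rec.signal[n_train:]
    truth = rec.true_phase[n_train:]
    theta = predict_series(sig, kind, model, mcfg, rate)
    theta_deg = to_protocol_deg(theta)
    refractory = int(round(cfg.refractory_s * rate))
    rows = []
    all_pred, all_true = [], []
    for target in cfg.target_phases_deg:
        events = []
        last = -refractory
        for now in range(sig.size):
            if not np.isfinite(theta_deg[now]):
                continue
            ev = phase_trigger(theta_deg[now], target, cfg.tolerance_deg,
                               last, refractory, now, model=kind)
            if ev is not None:
                events.append(ev)
                last = now
                if len(events) >= cfg.replications:
                    break
        if len(events) < cfg.replications:
            warnings.warn(
                f"incomplete session: subject {si}, {kind}, target {target} "
                f"deg collected {len(events)}/{cfg.replications} triggers")
        if not events:
            continue
        idx = np.array([min(ev.time_index + cfg.trigger_latency_samples,
                            sig.size - 1) for ev in events])
        pred = theta[[ev.time_index for ev in events]]
        true = truth[idx]
        summ = metrics.summarize_errors(pred, true)
        rows.append({"subject": si, "model": kind, "phase": float(target),
                     "snr": snr, **_summ_dict(summ)})
        all_pred.extend(pred)
        all_true.extend(true)
    if all_pred:
        summ = metrics.summarize_errors(all_pred, all_true)
        rows.insert(0, {"subject": si, "model": kind, "phase": "all",
                        "snr": snr, **_summ_dict(summ)})
    return rows


def report_to_rows(report) -> str:
    """Render the benchmark summaries as CSV text."""
    cols = ["subject", "model", "phase", "snr", "mean", "var", "sd", "mace",
            "acc", "n"]
    lines = [",".join(cols)]
    for row in report["summaries"]:
        lines.append(",".join(str(row[c]) for c in cols))
    return "\n".join(lines) + "\n"
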