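# eegphase

Real-time phase prediction for narrow-band EEG rhythms.

## The problem

Closed-loop neuromodulation (e.g. EEG-triggered TMS) needs the
*instantaneous phase* of an ongoing rhythm — typically the sensorimotor
μ rhythm, 8–13 Hz — at the very moment a stimulus is to be delivered. The
phase is defined through the analytic signal, θ(t) = arg 𝓗[x](t), but the
Hilbert transform needs a narrow-band input, and a zero-phase (two-pass)
bandpass filter reads *future* samples. In real time only a causal filter
is available, and a causal filter distorts amplitude and phase exactly at
the data edge where the prediction is needed. Every real-time phase
predictor is a strategy for working around that edge.

`eegphase` implements four such strategies behind one streaming interface:

* **EPN** — a small per-subject network: 250 first-order differences of
  the causal 0.5 s of raw EEG → average pooling (kernel 13) → fully
  connected layer (500 units, ReLU) → dropout (P = 0.9) → 2-dim output
  Z = (Re, Im), with θ̂ = arg(Z). Trained by MSE against the unit phasor
  (cos θ, sin θ) of the ground-truth phase (Adam; canonical schedule
  3000 epochs, lr 10⁻⁵, batch 512).
* **AR** — bandpass a 1-s causal window, discard the distorted tail, fit
  an AR(p) model by Yule–Walker, iterate X_t = Σ aᵢX_{t−i} forward past
  time 0, and read the Hilbert phase of the extension.
* **ETP** — learn the subject's individual rhythm frequency (IAF) and a
  phase bias from resting data; at run time interpolate the phase linearly
  from the last causally detected rhythm peak at the IAF cycle
  (T* = θ·T_adj/2π).
* **MLOF** — two linear branches over the same differenced input: K phasor
  candidates and a softmax gate; the output is the gated convex
  combination.

Around the predictors the package provides the full experimental chain:
BrainVision/EDF reading (via MNE), the 5-point Hjorth surface Laplacian,
resampling, zero-phase FIR + Hilbert ground-truth labeling, a synthetic
EEG generator (Kuramoto mean-field rhythm + 1/f background at calibrated
band-ratio SNR, with exact noise-free true phase), circular error
statistics (MEAN/VAR/SD/MACE/ACC), SNR regression, Wilcoxon model
comparison, and a replayed-stream emulator with phase-triggered events.

A detail worth knowing: accuracy is defined through the mean absolute
circular error, **ACC = 1 − MACE/π** (MACE in radians), so the two
statistics are always reported as a consistent pair.

## Worked example

```sh
python examples/03_train_epn.py
```

```
generating a 5-min subject at SNR 3 ...
windows: 417 train, 46 val, 103 test
trained in 3.1 s; loss 7.375 -> 0.100
held-out vs true rhythm phase: MEAN=+2.17 deg  VAR=0.018  SD=11.01 deg  MACE=0.159 rad  ACC=94.93%  (n=103)
```

One synthetic subject (5 min at 1000 Hz, band-ratio SNR ≈ 3) is resampled
to 500 Hz, cut into 6.16-s epochs, and the network is trained at desk
scale (300 epochs). Held out is the final minute; each epoch-center
prediction is scored against the *noise-free* rhythm phase. MEAN ≈ 0 means
the predictor is unbiased; SD 11° and ACC 94.9 % mean the causal network
recovers, to within ~11°, the phase that an offline non-causal analysis
would only deliver after the fact.

The other examples cover the simulator (`01`), ground-truth labeling
(`02`), the comparators (`04`), the multi-subject offline benchmark with
statistics (`05`), and the streamed, phase-triggered replay (`06`). A thin
CLI mirrors the same steps (`eegphase simulate|preprocess|dataset|train|
evaluate|replay|compare`).

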