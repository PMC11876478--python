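# Methods

This note records the models implemented by `eegphase`, the conventions
and numerical choices behind them, what the synthetic data does and does
not emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signals, conventions, units

All amplitudes are microvolts. All internal phases are the Hilbert angle
of the real signal in (−π, π], so a cosine peak sits at 0 rad; the
protocol-facing convention used for targets and reports (rising edge 0°,
peak 90°, falling edge 180°, trough 270°) is obtained by adding 90°
(mod 360°) at the presentation layer only (`pipeline.to_protocol_deg`).
Keeping a single internal convention and one explicit mapping avoids the
classic off-by-90° class of bugs when peak-based (ETP) and
analytic-signal-based predictors are mixed.

"Time 0" of an epoch is the first sample of its second half: 0-based
index 1540 of a 3080-sample window (6.16 s at 500 Hz, 3.08 s at
1000 Hz). Epochs are cut with an overlap-augmentation schedule of
0–640 samples in steps of 64; windows from all schedule entries are
pooled and deduplicated by start index. The leading 4 minutes of a 5-min
resting recording are the training range (split 90/10 chronologically
into train/validation), the final minute is the test range; the two never
share a sample.

## Ground-truth labeling and why it is non-causal

The label of an epoch is the Hilbert phase at its center after a two-pass
(forward–backward) zero-phase FIR bandpass, 8–13 Hz, 769 taps at the
working rate, symmetric ("even") edge padding of one filter length. The
center is ±1.54 s from either edge — outside the filter's edge-distorted
region — so the label is free of causal distortion. This chain cannot run
in real time (it reads the future); the whole point of the predictors is
to approximate its output causally.

Filter design is windowed-sinc (Hamming) via `scipy.signal.firwin`; an
even tap count is promoted to the next odd number, since a type-I linear
phase FIR is required for a bandpass.

## Model inputs (strictly causal)

* EPN / MLOF: the 251 raw samples from −0.5 s to 0 s inclusive
  (indices 1290…1540), differenced to 250 values; the last difference
  uses the time-0 sample. Differencing removes slow electrode drift and
  flattens the 1/f spectrum, which is the only input conditioning used.
* AR: the 500 raw samples from −1.0 s to 0 s (500 Hz).
* ETP: the full causal first half of the 1000-Hz window (1540 samples).

No input may read an index greater than the center; this is enforced by a
poisoned-future test at both window and stream level.

## EPN

Forward pass: length-preserving moving average with kernel s = 13 (the
tail is repeat-padded), fully connected layer of 500 ReLU units, dropout
with P = 0.9 (inverted scaling at train time, inactive at inference),
linear output to Z ∈ R². Phase decoding is θ̂ = atan2(Z_im, Z_re).

Training target: the unit phasor (cos θ, sin θ). With an MSE loss this
is a proper phase regression — the loss is minimized by the circular mean
direction — and matches the 2-dim output. An amplitude-bearing target
(the analytic signal at time 0) was considered and rejected as canonical:
it couples phase accuracy to amplitude prediction, which the evaluation
does not score.

Optimization: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), MSE over shuffled
mini-batches. The canonical schedule is 3000 epochs, lr 1e−5, batch 512.
The **desk-scale schedule** used throughout the tests and the acceptance
script is 300 epochs with lr 1e−3 (the standard Adam rate): the canonical
rate belongs to the long schedule and would leave a 300-epoch run
essentially untrained. Both are plain config values
(`EPNConfig` / `EPNConfig.desk_scale`).

Everything — initialization (Glorot-uniform), batch shuffling, dropout
masks — derives from one `numpy` generator seeded from the config, so
training is bit-reproducible per seed. Forward/backward passes and Adam
are explicit numpy; the model is four small arrays, and weights serialize
to `.npz` with a JSON config string.

## AR comparator

The 1-s raw window is band-filtered with a short two-pass FIR (order 64;
a long filter would distort, and force discarding, too much of the
window), the trailing 64 samples are discarded as edge-distorted, an
AR(30) model is fitted to the remainder by Yule–Walker on the biased
autocovariance (`statsmodels.yule_walker`, `demean=False`), and the
recurrence is iterated forward noise-free to regenerate the tail and
0.256 s beyond time 0. The Hilbert phase of the concatenation is read at
the time-0 sample. The 0.256-s extension places the Hilbert evaluation
point ~2.5 rhythm cycles away from the series end, where the analytic
signal is clean; shorter extensions measurably bias the phase on pure
tones. An explosive-iteration guard (|x| > 10⁶ × input RMS) converts
unstable fits into a clear error.

Note on the exactness check: a pure cosine satisfies
x_t = 2cos(ω)x_{t−1} − x_{t−2} exactly, but the biased autocovariance
shrinks the estimated poles at finite n (and the Toeplitz system of a
noiseless sinusoid is near-singular), so the Yule–Walker solution
approaches the exact recurrence only as the record grows; the test uses a
10⁵-sample tone, where the one-step residual is below 10⁻³ RMS.

## ETP comparator

From the training range: the IAF is the Welch-PSD peak (10-s Hann
segments, 50 % overlap, parabolic interpolation on log power) within
8–13 Hz; a no-rhythm error is raised if the band peak does not rise to at
least twice the aperiodic trend fitted by the same routine the simulator
uses. The phase bias is the offset, on a 1° grid (ties toward zero),
minimizing the mean absolute circular error between causally interpolated
phases and the ground-truth phase over evaluation points every 100 ms.

At run time the causal history is filtered with a causal FIR (order 128
at 1000 Hz), peaks are detected with minimum separation of half an IAF
cycle, peak times are compensated by the filter group delay, and the
phase at time 0 is 2π·IAF·Δt + bias from the last confirmed peak (a peak
is confirmed one sample after it occurs). Quantization of peak times to
the sampling grid bounds the error by one sample of phase advance
(3.6° at 10 Hz / 1 kHz) on a perfectly periodic rhythm.

## MLOF comparator

Branch A maps the 250-dim input linearly to K = 8 phasor candidates
(2K values); branch B maps it to K softmax gates; the output is
Z = Σ_k g_k c_k, always inside the candidates' convex hull. Training is
identical to the EPN (MSE on the unit phasor, Adam, same schedules). The
original architecture's exact layer widths are not recoverable from the
sources available here; K and the linear-candidate choice are this
package's reading, kept deliberately minimal, and configurable.

## Synthetic EEG

The simulator separates "rhythm" from "truth-destroying background":

* **Rhythm**: a Kuramoto ensemble, dθᵢ/dt = ωᵢ + (K/N)Σⱼ sin(θⱼ−θᵢ),
  N = 100, natural frequencies N(f₀, 0.5²) Hz with the subject's f₀ drawn
  from N(10, 0.5²), coupling 8 rad/s — partial synchrony (order parameter
  ≈ 0.6), so the mean field waxes and wanes like a real μ rhythm. Euler
  integration at the signal rate (step-halving changes the rhythm RMS by
  < 1 %, checked in tests), 2-s burn-in, then scaled to 10 µV.
  The **true phase** is the Hilbert angle of this noise-free mean field,
  stored before any noise is added — so it is invariant to the noise
  level, which is exactly what distinguishes it from filter-based ground
  truth.
* **Background**: Gaussian noise spectrally shaped by inverse FFT to the
  aperiodic model log₁₀PSD(f) = b − log₁₀(k + f^χ), with the subject's χ
  drawn from N(1.5, 0.3²). The companion `fit_aperiodic` routine fits the
  same model by robust iterative least squares (points > 2.5 robust SD
  above the fit — oscillatory peaks — are trimmed and the fit repeated).
* **Composition**: noise amplitude is solved from the band powers of the
  two components and refined by bisection until the realized band-ratio
  SNR (mean Welch PSD 8–13 Hz ÷ mean PSD 2–45 Hz, 1-s Hann segments,
  50 % overlap — a ratio that calibrates white noise to 1) is within
  10 % of the target. Targets above the rhythm's noiseless ceiling raise
  an error.

What this does **not** emulate: volume conduction and multichannel
structure (the simulation is the single post-Laplacian channel the models
consume), non-stationary spectral drift, artifacts (blinks, muscle, TMS
pulses), and per-subject aperiodic/rhythm parameters fitted from any
real cohort — the distributions above are field-plausible stand-ins.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behavior of the predictors under controlled SNR, not
performance numbers transferable to any particular human dataset.

## Evaluation

For signed wrapped errors dᵢ with mean resultant R̄:
MEAN = arg(mean eⁱᵈ), VAR = 1 − |R̄|, SD = √(−2 ln(1 − VAR)),
MACE = mean |dᵢ|, ACC = 1 − MACE/π. The ACC identity is the only reading
under which accuracy and MACE form a consistent pair, and it is asserted
to 1e−12 on random error sets. Degenerate conventions: an exactly zero
resultant reports MEAN = 0, VAR = 1, SD = +∞.

Accuracy~SNR dependence is ordinary least squares (accuracy dependent,
SNR independent) with the small-sample adjusted R²; model comparison is
the two-sided Wilcoxon signed-rank test per pair with Bonferroni
correction (multiply by the number of pairs, cap at 1); identical paired
scores report p = 1.

## Streaming and triggers

`StreamPredictor` consumes chunks and emits one phase estimate per sample
(NaN during warm-up: 251 samples for EPN/MLOF, 500 for AR, 1540 for ETP).
`predict_series` computes the same estimates in batch and is
bit-identical to the streamed path: EPN/MLOF inference is evaluated
row-by-row on purpose, because batched BLAS changes floating-point
accumulation order; the ETP batch path replicates the incremental
peak-confirmation rule exactly. A trigger fires when the predicted
protocol phase is within tolerance (default 5°) of the target and the
refractory period (default 1 s) has elapsed; a configurable integer
sample delay models hardware trigger latency (default 0). Sessions that
cannot collect their replication count in the available data warn with
counts rather than failing.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: 5-min
synthetic subjects (300 s at 1000 Hz, ~3 s to generate), cohorts of 5
subjects at target SNR 2, EPN/MLOF trained 300 epochs (~3 s per model
per subject), six recomposed SNR levels (1.2–4.0) for the accuracy~SNR
slope. These sizes were chosen so a full benchmark is a coffee-break
computation on a single core while leaving every distributional property
(partial synchrony, 1/f background, calibrated SNR) at its stated value;
the canonical 3000-epoch schedule remains available in the configs.

## Known limitations

* No ONNX export; weights serialize natively (`.npz` + JSON).
* No artifact handling or channel-quality checks; inputs are assumed to
  be clean resting EEG.
* ETP's batch/stream equivalence relies on `find_peaks` distance pruning
  agreeing between prefix and full series; pathological near-tie peak
  pairs could in principle differ at the pruning margin (the incremental
  predictor is the causal reference).
* The AR comparator's accuracy depends on its inner filter and discard
  length; the defaults (64-tap, discard = taps) follow the shortness
  constraint discussed above and are exposed in `ARConfig`.
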