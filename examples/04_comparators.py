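"""The three comparator predictors on a noiseless 10 Hz rhythm.

AR forward-extends a Yule-Walker fit past the causally distorted filter
edge; ETP interpolates from the last detected rhythm peak at the learned
individual frequency; MLOF gates K candidate phasors with a softmax.
On a pure tone, AR and ETP should be nearly exact.
"""

import numpy as np

from eegphase import baselines
from eegphase._utils import wrap_phase

rate = 500.0
phi = 0.9
t = (np.arange(500) - 499) / rate  # 1-s window, last sample is time 0
x = np.cos(2 * np.pi * 10 * t + phi)
th = baselines.ar_phase_from_raw(x, baselines.ARConfig(), rate)
print(f"AR:  true {np.degrees(phi):6.1f} deg, predicted "
      f"{np.degrees(th):6.1f} deg, error "
      f"{np.degrees(wrap_phase(th - phi)):+5.2f} deg")

rate = 1000.0
tt = np.arange(int(240 * rate)) / rate
tone = np.cos(2 * np.pi * 10.0 * tt)
truth = wrap_phase(2 * np.pi * 10.0 * tt)
state = baselines.etp_learn(tone, rate, ground_truth_phase=truth)
print(f"ETP: learned IAF {state.iaf:.2f} Hz, cycle {state.t_adj_ms:.1f} ms, "
      f"bias {np.degrees(state.phase_bias):+.2f} deg")
t_eval = 100030  # 30 ms past a rhythm peak
th = baselines.etp_predict_phase(tone[:t_eval], state, rate)
print(f"ETP: 30 ms after a peak -> {np.degrees(th):6.1f} deg "
      f"(expected {0.3 * 360:.0f} deg)")
print(f"ETP: time to reach a half-cycle target: "
      f"{state.target_offset_ms(np.pi):.1f} ms")

cfg = baselines.MLOFConfig(n_banks=4)
w = baselines.MLOFWeights.init(cfg, np.random.default_rng(0))
z, gates = baselines.mlof_forward(np.random.default_rng(1).normal(size=250),
                                  w, cfg)
print(f"MLOF: gates {np.round(gates, 3)} (sum {gates.sum():.6f}), "
      f"output Z = {np.round(z, 3)}")
# Untrained MLOF gates are near-uniform; training sharpens them onto the
# frequency bank that matches the subject's rhythm.
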