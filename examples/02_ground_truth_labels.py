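"""Label the instantaneous phase at the center of a 6.16-s epoch.

Ground truth for training and scoring is defined offline: a two-pass
zero-phase FIR bandpass (8-13 Hz, 769 taps) followed by the Hilbert
transform, read at the epoch center - a sample far enough from both edges
that the filter leaves it undistorted.  On a noiseless tone the label must
recover the constructed phase almost exactly.
"""

import numpy as np

from eegphase import windowing
from eegphase._utils import wrap_phase

rate = 500.0
print("phase phi | label  | error (rad)")
worst = 0.0
for phi in np.linspace(-np.pi, np.pi, 8, endpoint=False):
    t = (np.arange(windowing.WINDOW_LEN) - windowing.CENTER_INDEX) / rate
    w = windowing.TrialWindow(raw=np.cos(2 * np.pi * 10 * t + phi))
    theta = windowing.label_phase(w)
    err = wrap_phase(theta - phi)
    worst = max(worst, abs(err))
    print(f"{phi:+9.3f} | {theta:+6.3f} | {err:+.5f}")
print(f"\nworst labeling error: {worst:.5f} rad "
      "(the non-causal chain is essentially exact on a clean rhythm)")
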