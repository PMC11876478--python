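"""Shared angular helpers.

Internal phase convention throughout the library: the Hilbert angle of the
real signal, so a cosine peak sits at 0 rad.  Angles live in (-pi, pi].
The protocol-facing convention (rising edge 0 deg, peak 90 deg) is a
presentation mapping applied only in :mod:`eegphase.pipeline`.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(theta):
    """Wrap angle(s) in radians to the half-open interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -(np.mod(np.pi - theta, TWO_PI) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def circ_dist(a, b):
    """Signed circular difference a - b, wrapped to (-pi, pi]."""
    return wrap_phase(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circ_dist_deg(a, b):
    """Absolute circular distance between angles in degrees, in [0, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    return np.minimum(d, 360.0 - d)
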