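"""Shared fixtures: programmatic EEG file writers and small signals."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest


def tone(freq, rate, n, phi=0.0, amp=1.0):
    """cos(2 pi f t + phi) sampled at `rate` for n samples."""
    t = np.arange(n) / rate
    return amp * np.cos(2 * np.pi * freq * t + phi)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Minimal EDF writer (synthetic fixture files, built at test time)
# ---------------------------------------------------------------------------

def write_edf(path, data_uv, rate, labels):
    """Write a minimal valid EDF file: int16 records of 1 s each.

    ``data_uv``: (n_channels, n_samples) in microvolts; n_samples must be a
    multiple of ``rate``.
    """
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data_uv.shape
    spr = int(rate)  # samples per 1-s record
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp

    pmin = np.floor(data_uv.min(axis=1)) - 1
    pmax = np.ceil(data_uv.max(axis=1)) + 1
    dmin, dmax = -32768, 32767

    def pad(s, width):
        s = str(s)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 * (1 + n_ch), 8), pad("", 44),
        pad(n_rec, 8), pad("1", 8), pad(n_ch, 4),
    ])
    hdr += b"".join(pad(lbl, 16) for lbl in labels)
    hdr += b"".join(pad("", 80) for _ in labels)
    hdr += b"".join(pad("uV", 8) for _ in labels)
    hdr += b"".join(pad(f"{v:g}", 8) for v in pmin)
    hdr += b"".join(pad(f"{v:g}", 8) for v in pmax)
    hdr += b"".join(pad(dmin, 8) for _ in labels)
    hdr += b"".join(pad(dmax, 8) for _ in labels)
    hdr += b"".join(pad("", 80) for _ in labels)
    hdr += b"".join(pad(spr, 8) for _ in labels)
    hdr += b"".join(pad("", 32) for _ in labels)

    dig = np.empty_like(data_uv, dtype=np.int16)
    for c in range(n_ch):
        scaled = (data_uv[c] - pmin[c]) / (pmax[c] - pmin[c])
        dig[c] = np.round(scaled * (dmax - dmin) + dmin).astype(np.int16)

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(dig[c, r * spr:(r + 1) * spr].tobytes())
    return Path(path)


# ---------------------------------------------------------------------------
# Minimal BrainVision triplet writer
# ---------------------------------------------------------------------------

def write_brainvision(stem: Path, data_uv, rate, labels):
    """Write .vhdr/.vmrk/.eeg with IEEE float32 multiplexed data in uV."""
    stem = Path(stem)
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=np.float32))
    n_ch = data_uv.shape[0]
    sampling_interval_us = 1e6 / rate
    vhdr = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem.name}.eeg",
        f"MarkerFile={stem.name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, lbl in enumerate(labels, 1):
        vhdr.append(f"Ch{i}={lbl},,1,µV")
    (stem.parent / f"{stem.name}.vhdr").write_text("\n".join(vhdr) + "\n",
                                                   encoding="utf-8")
    vmrk = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem.name}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20200101000000000000",
    ]
    (stem.parent / f"{stem.name}.vmrk").write_text("\n".join(vmrk) + "\n",
                                                   encoding="utf-8")
    data_uv.T.astype("<f4").tofile(stem.parent / f"{stem.name}.eeg")
    return stem.parent / f"{stem.name}.vhdr"
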