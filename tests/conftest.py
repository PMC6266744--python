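"""Shared fixtures: toy recordings and a minimal programmatic EDF writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from eegvrp.types import CHANNELS_32, MultichannelRecording


@pytest.fixture
def make_recording():
    """Factory for small multichannel recordings with T7/T8 present."""

    def _make(
        samples: np.ndarray,
        labels=None,
        fs_hz: float = 512.0,
        subject_id: str = "S01",
        visit: int = 1,
    ) -> MultichannelRecording:
        samples = np.asarray(samples, dtype=float)
        if labels is None:
            n = samples.shape[0]
            labels = CHANNELS_32[:n] if n <= 32 else tuple(
                f"CH{i}" for i in range(n)
            )
            if n >= 2 and ("T7" not in labels or "T8" not in labels):
                labels = ("T7", "T8") + tuple(
                    lbl for lbl in labels if lbl not in ("T7", "T8")
                )[: n - 2]
        return MultichannelRecording(
            samples=samples,
            channel_labels=tuple(labels),
            fs_hz=fs_hz,
            subject_id=subject_id,
            visit=visit,
        )

    return _make


@pytest.fixture
def sine_recording(make_recording):
    """32-channel 10 Hz unit sinusoid, 8 s at 512 Hz."""
    fs = 512.0
    t = np.arange(int(8 * fs)) / fs
    x = np.tile(np.sin(2 * np.pi * 10.0 * t), (32, 1))
    return make_recording(x, labels=CHANNELS_32, fs_hz=fs)


def write_minimal_edf(path, signals: np.ndarray, labels, fs_hz: int) -> None:
    """Write a bare-bones EDF file: one data record, int16 samples.

    Physical range is +-200 uV mapped onto the full digital range, so
    quantization error is ~6e-3 uV.
    """
    n_ch, n_samp = signals.shape
    assert n_samp == fs_hz, "one 1-second record"
    phys_min, phys_max = -200.0, 200.0
    dig_min, dig_max = -32768, 32767

    def pad(s, width):
        return s.ljust(width)[:width].encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("synthetic subject", 80),
            pad("synthetic recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad("1", 8),  # n data records
            pad("1", 8),  # record duration s
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, list(labels)),
        (80, [""] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [str(phys_min)] * n_ch),
        (8, [str(phys_max)] * n_ch),
        (8, [str(dig_min)] * n_ch),
        (8, [str(dig_max)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(n_samp)] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_hdr = b"".join(
        b"".join(pad(v, w) for v in vals) for w, vals in fields
    )
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((signals - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for ch in range(n_ch):
            fh.write(struct.pack(f"<{n_samp}h", *digital[ch]))
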