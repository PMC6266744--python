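"""EEG preprocessing: T7/T8 re-referencing, zero-phase IIR bandpass,
epoching and amplitude-threshold artifact rejection.

The chain mirrors standard infant resting-state practice: every channel is
re-referenced to the average of the temporal pair T7/T8, bandpassed
0.3-30 Hz with a 4th-order Butterworth applied forward-backward (zero
phase), cut into non-overlapping 2 s epochs, and epochs containing any
sample above an absolute amplitude threshold (default 200 uV) are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import signal

from .types import EpochSet, MultichannelRecording

__all__ = [
    "rereference",
    "bandpass",
    "epoch",
    "reject_noisy",
    "preprocess_recording",
]

#: Sessions retaining less than this are flagged (not excluded by default).
MIN_RETAINED_S = 14.0


def rereference(rec: MultichannelRecording) -> MultichannelRecording:
    """Subtract the instantaneous mean of T7 and T8 from every channel."""
    for lbl in ("T7", "T8"):
        if lbl not in rec.channel_labels:
            raise ValueError(
                f"re-referencing requires channel {lbl!r}; "
                f"recording has {list(rec.channel_labels)}"
            )
    ref = 0.5 * (rec.channel("T7") + rec.channel("T8"))
    return rec.with_samples(rec.samples - ref[None, :], rereferenced=True)


def bandpass(
    rec: MultichannelRecording,
    low_hz: float = 0.3,
    high_hz: float = 30.0,
    order: int = 4,
) -> MultichannelRecording:
    """Zero-phase Butterworth bandpass, length-preserving.

    The filter is applied forward and backward (``sosfiltfilt``) so spectral
    estimates downstream are phase-undistorted; the effective magnitude
    response is the squared one-pass response.
    """
    nyq = rec.fs_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"high cutoff {high_hz} Hz must be below Nyquist ({nyq} Hz)"
        )
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("recording contains non-finite samples")
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rec.fs_hz, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.with_samples(filtered)


def epoch(rec: MultichannelRecording, epoch_length_s: float = 2.0) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; drop the trailing partial."""
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    n_per = int(round(epoch_length_s * rec.fs_hz))
    n_ep = rec.n_samples // n_per
    if n_ep < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s is shorter than one "
            f"{epoch_length_s} s epoch"
        )
    used = n_ep * n_per
    eps = rec.samples[:, :used].reshape(rec.n_channels, n_ep, n_per)
    return EpochSet(
        epochs=np.swapaxes(eps, 0, 1),
        epoch_length_s=epoch_length_s,
        fs_hz=rec.fs_hz,
        channel_labels=rec.channel_labels,
        n_discarded_samples=rec.n_samples - used,
        subject_id=rec.subject_id,
        visit=rec.visit,
    )


def reject_noisy(
    eps: EpochSet,
    amplitude_threshold_uv: float = 200.0,
    min_retained_s: float = MIN_RETAINED_S,
) -> EpochSet:
    """Drop epochs where any channel sample exceeds |threshold|.

    Warns (without failing) if the retained duration falls below
    ``min_retained_s``; raises if no epoch survives.
    """
    if amplitude_threshold_uv <= 0:
        raise ValueError("amplitude threshold must be positive")
    peak = np.abs(eps.epochs).max(axis=(1, 2))
    keep = eps.retained_mask & (peak <= amplitude_threshold_uv)
    if not keep.any():
        raise ValueError(
            "all epochs exceed the rejection threshold; session unusable"
        )
    out = replace(eps, retained_mask=keep)
    if out.retained_duration_s < min_retained_s:
        warnings.warn(
            f"retained duration {out.retained_duration_s:.1f} s is below "
            f"{min_retained_s:.0f} s for session "
            f"{eps.subject_id}/{eps.visit}",
            UserWarning,
            stacklevel=2,
        )
    return out


def preprocess_recording(
    rec: MultichannelRecording,
    low_hz: float = 0.3,
    high_hz: float = 30.0,
    epoch_length_s: float = 2.0,
    amplitude_threshold_uv: float = 200.0,
    min_retained_s: float = MIN_RETAINED_S,
) -> EpochSet:
    """Full chain: rereference -> bandpass -> epoch -> reject."""
    rec = rereference(rec)
    rec = bandpass(rec, low_hz=low_hz, high_hz=high_hz)
    eps = epoch(rec, epoch_length_s=epoch_length_s)
    return reject_noisy(
        eps,
        amplitude_threshold_uv=amplitude_threshold_uv,
        min_retained_s=min_retained_s,
    )
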