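"""Spectral features: Welch PSD, relative power, and the variance of
relative power (VRP) statistic.

VRP is a scalar per session: each electrode's relative-power spectrum over
0-30 Hz is summarized by one number (its peak relative power by default),
and VRP is the sample standard deviation of those summaries across the 32
electrodes.  Higher VRP means the electrodes disagree more about where
spectral power concentrates — a cross-channel spectral-heterogeneity
statistic.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from . import preprocessing
from .types import (
    EpochSet,
    MultichannelRecording,
    PowerSpectrum,
    RelativePowerMatrix,
    SessionFeature,
)

__all__ = [
    "welch_psd",
    "relative_power",
    "electrode_summary",
    "vrp",
    "session_feature",
    "VRPTransformer",
]


def welch_psd(
    eps: EpochSet,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window: str = "hamming",
) -> PowerSpectrum:
    """Averaged-periodogram PSD over all retained epochs.

    Each retained epoch is tapered and transformed with Welch's method
    (segments of ``segment_s`` seconds, fractional overlap
    ``overlap_frac``); the per-epoch spectra are then averaged with equal
    weight.  Frequency spacing is ``1/segment_s``.
    """
    if eps.n_retained < 1:
        raise ValueError("no retained epochs to estimate a PSD from")
    if segment_s > eps.epoch_length_s + 1e-12:
        raise ValueError(
            f"Welch segment ({segment_s} s) cannot exceed the epoch "
            f"length ({eps.epoch_length_s} s)"
        )
    nperseg = int(round(segment_s * eps.fs_hz))
    noverlap = int(round(overlap_frac * nperseg))
    freqs, psds = signal.welch(
        eps.retained,
        fs=eps.fs_hz,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PowerSpectrum(
        psd=psds.mean(axis=0),
        freqs_hz=freqs,
        channel_labels=eps.channel_labels,
        welch_params={
            "segment_s": segment_s,
            "overlap_frac": overlap_frac,
            "window": window,
            "n_epochs_averaged": eps.n_retained,
        },
    )


def relative_power(
    ps: PowerSpectrum, fmin: float = 0.0, fmax: float = 30.0
) -> RelativePowerMatrix:
    """Normalize each channel's PSD to unit sum over the [fmin, fmax] band."""
    band = (ps.freqs_hz >= fmin - 1e-9) & (ps.freqs_hz <= fmax + 1e-9)
    if band.sum() < 2:
        raise ValueError(
            f"band [{fmin}, {fmax}] Hz covers {int(band.sum())} bins; need >= 2"
        )
    sub = ps.psd[:, band]
    totals = sub.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        names = [ps.channel_labels[i] for i in bad]
        raise ValueError(f"zero total band power in channel(s) {names}")
    return RelativePowerMatrix(
        rp=sub / totals[:, None],
        freqs_hz=ps.freqs_hz[band],
        channel_labels=ps.channel_labels,
    )


def electrode_summary(
    rpm: RelativePowerMatrix, mode: str = "peak"
) -> np.ndarray:
    """One scalar per electrode: peak (max over bins) or mean relative power."""
    if rpm.rp.shape[1] == 0:
        raise ValueError("empty frequency band")
    if mode == "peak":
        return rpm.rp.max(axis=1)
    if mode == "mean":
        return rpm.rp.mean(axis=1)
    raise ValueError(f"summary mode must be 'peak' or 'mean', got {mode!r}")


def vrp(summary: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) of per-electrode summaries."""
    arr = np.asarray(summary, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D vector of >= 2 electrode summaries")
    if not np.all(np.isfinite(arr)):
        raise ValueError("electrode summaries must be finite")
    return float(np.std(arr, ddof=1))


def session_feature(
    eps: EpochSet,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    fmin: float = 0.0,
    fmax: float = 30.0,
    summary_mode: str = "peak",
) -> SessionFeature:
    """EpochSet -> SessionFeature: Welch PSD, relative power, summary, VRP."""
    ps = welch_psd(eps, segment_s=segment_s, overlap_frac=overlap_frac)
    rpm = relative_power(ps, fmin=fmin, fmax=fmax)
    summ = electrode_summary(rpm, mode=summary_mode)
    return SessionFeature(
        vrp=vrp(summ),
        per_electrode_summary=summ,
        summary_mode=summary_mode,
        subject_id=eps.subject_id,
        visit=eps.visit,
        retained_duration_s=eps.retained_duration_s,
        n_epochs_total=eps.n_epochs,
        n_epochs_retained=eps.n_retained,
    )


class VRPTransformer(BaseEstimator, TransformerMixin):
    """Recordings -> VRP feature column, scikit-learn transformer style.

    Wraps the full preprocessing + spectral chain: T7/T8 re-referencing,
    zero-phase Butterworth bandpass, epoching, amplitude rejection, Welch
    PSD, relative power over [fmin, fmax] and the cross-electrode standard
    deviation of the per-electrode summary.  Stateless (``fit`` learns
    nothing); ``transform`` accepts an iterable of
    :class:`~eegvrp.types.MultichannelRecording` or
    :class:`~eegvrp.types.EpochSet` and returns an (n, 1) float array.

    Parameters
    ----------
    low_hz, high_hz : float
        Bandpass corner frequencies (Hz).
    epoch_length_s : float
        Non-overlapping epoch length (s).
    amplitude_threshold_uv : float
        Absolute rejection threshold (uV); epochs with any sample beyond
        it are dropped.
    segment_s, overlap_frac : float
        Welch segment length (s) and fractional overlap.
    fmin, fmax : float
        Relative-power normalization band (Hz).
    summary_mode : {'peak', 'mean'}
        Per-electrode scalar summary of the relative-power spectrum.
    """

    def __init__(
        self,
        low_hz: float = 0.3,
        high_hz: float = 30.0,
        epoch_length_s: float = 2.0,
        amplitude_threshold_uv: float = 200.0,
        segment_s: float = 2.0,
        overlap_frac: float = 0.5,
        fmin: float = 0.0,
        fmax: float = 30.0,
        summary_mode: str = "peak",
    ) -> None:
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.epoch_length_s = epoch_length_s
        self.amplitude_threshold_uv = amplitude_threshold_uv
        self.segment_s = segment_s
        self.overlap_frac = overlap_frac
        self.fmin = fmin
        self.fmax = fmax
        self.summary_mode = summary_mode

    def fit(self, X: Iterable, y: Optional[Sequence] = None) -> "VRPTransformer":
        self.n_features_in_ = 1
        return self

    def transform_sessions(self, X: Iterable) -> list[SessionFeature]:
        """Like :meth:`transform` but returns full per-session provenance."""
        out = []
        for item in X:
            if isinstance(item, MultichannelRecording):
                eps = preprocessing.preprocess_recording(
                    item,
                    low_hz=self.low_hz,
                    high_hz=self.high_hz,
                    epoch_length_s=self.epoch_length_s,
                    amplitude_threshold_uv=self.amplitude_threshold_uv,
                )
            elif isinstance(item, EpochSet):
                eps = item
            else:
                raise TypeError(
                    "expected MultichannelRecording or EpochSet, "
                    f"got {type(item).__name__}"
                )
            out.append(
                session_feature(
                    eps,
                    segment_s=self.segment_s,
                    overlap_frac=self.overlap_frac,
                    fmin=self.fmin,
                    fmax=self.fmax,
                    summary_mode=self.summary_mode,
                )
            )
        return out

    def transform(self, X: Iterable) -> np.ndarray:
        feats = self.transform_sessions(X)
        return np.array([[f.vrp] for f in feats])
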