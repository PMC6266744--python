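"""Core in-memory containers for the resting-state EEG VRP pipeline.

Everything downstream operates on these light dataclasses: a raw
multichannel recording, the epoched/cleaned view of it, Welch spectra,
relative-power matrices and the per-session scalar feature (variance of
relative power, VRP).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Biosemi 32-electrode cap labels (standard 10/20 extension).  The
#: temporal pair T7/T8 must be present: it is the re-referencing montage.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)


@dataclass
class MultichannelRecording:
    """Time-domain EEG, channels x samples, in microvolts."""

    samples: np.ndarray
    channel_labels: tuple[str, ...]
    fs_hz: float
    subject_id: Optional[str] = None
    visit: Optional[int] = None
    rereferenced: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray, **kw) -> "MultichannelRecording":
        return replace(self, samples=samples, **kw)


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs cut from one recording.

    ``retained_mask`` marks epochs that survived artifact rejection; the
    trailing partial segment of the recording (if any) is recorded in
    ``n_discarded_samples`` so that retained + rejected + remainder
    accounts for every input sample.
    """

    epochs: np.ndarray  # (n_epochs, n_channels, epoch_samples)
    epoch_length_s: float
    fs_hz: float
    channel_labels: tuple[str, ...]
    retained_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_discarded_samples: int = 0
    subject_id: Optional[str] = None
    visit: Optional[int] = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.retained_mask is None:
            self.retained_mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if self.retained_mask.shape != (self.epochs.shape[0],):
            raise ValueError("retained_mask must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    @property
    def retained_duration_s(self) -> float:
        return self.n_retained * self.epoch_length_s

    @property
    def retained(self) -> np.ndarray:
        return self.epochs[self.retained_mask]


@dataclass
class PowerSpectrum:
    """Welch power spectral density, channels x frequency bins (uV^2/Hz)."""

    psd: np.ndarray
    freqs_hz: np.ndarray
    channel_labels: tuple[str, ...]
    welch_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.psd.ndim != 2 or self.psd.shape[1] != self.freqs_hz.size:
            raise ValueError("psd must be channels x len(freqs_hz)")
        if np.any(self.psd < 0):
            raise ValueError("PSD values must be nonnegative")
        if self.freqs_hz.size >= 2:
            d = np.diff(self.freqs_hz)
            if np.any(d <= 0) or not np.allclose(d, d[0]):
                raise ValueError("freqs_hz must be uniformly increasing")


@dataclass
class RelativePowerMatrix:
    """Per-channel relative power over a band: rows are nonnegative, sum to 1."""

    rp: np.ndarray
    freqs_hz: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.rp = np.asarray(self.rp, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.rp.ndim != 2 or self.rp.shape[1] != self.freqs_hz.size:
            raise ValueError("rp must be channels x len(freqs_hz)")
        sums = self.rp.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("each relative-power row must sum to 1")
        if np.any(self.rp < -1e-12) or np.any(self.rp > 1 + 1e-12):
            raise ValueError("relative power must lie in [0, 1]")


@dataclass
class SessionFeature:
    """Scalar VRP for one session plus its provenance."""

    vrp: float
    per_electrode_summary: np.ndarray
    summary_mode: str
    subject_id: Optional[str] = None
    visit: Optional[int] = None
    retained_duration_s: Optional[float] = None
    n_epochs_total: Optional[int] = None
    n_epochs_retained: Optional[int] = None

    def __post_init__(self) -> None:
        self.per_electrode_summary = np.asarray(
            self.per_electrode_summary, dtype=float
        )
        if self.vrp < 0:
            raise ValueError("vrp is a standard deviation; it cannot be negative")
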