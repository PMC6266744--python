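"""Synthetic infant resting-state EEG and cohort generator.

The generator emulates the statistical structure the VRP analysis assumes:

* per channel, a 1/f^alpha aperiodic background plus one narrowband
  oscillation (default 6 Hz, the infant alpha/theta range) plus white
  sensor noise, with optional high-amplitude artifact bursts at Poisson
  times;
* cross-channel *heterogeneity* controlled by a single spread parameter
  sigma_h that jitters each channel's oscillation peak frequency (Hz) and
  log-amplitude around the group mean — larger sigma_h makes the
  electrodes' relative-power spectra disagree more, which is exactly what
  the VRP statistic measures;
* a two-group cohort (typically developing vs at-risk) whose groups differ
  only in sigma_h by default, with ages uniform over each group's range,
  a second visit 60 days later for a subset of subjects, and Bayley-style
  developmental scores generated as a linear function of age, group and
  the session's ground-truth expected VRP plus Gaussian noise.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import CHANNELS_32, MultichannelRecording

__all__ = [
    "ChannelProfile",
    "SimulationConfig",
    "GeneratedCohort",
    "default_bayley_coefficients",
    "draw_channel_profiles",
    "generate_recording",
    "expected_peak_relative_power",
    "expected_vrp",
    "generate_cohort",
]

#: Bayley-like outcomes the generator emits directly.  Total raw is the sum
#: of the five raw subscales; percentile ranks are derived from composites.
RAW_OUTCOMES = (
    "bayley_raw_fine_motor",
    "bayley_raw_gross_motor",
    "bayley_raw_receptive_lang",
    "bayley_raw_expressive_lang",
    "bayley_raw_cognitive",
)
COMPOSITE_OUTCOMES = (
    "composite_cognitive",
    "composite_language",
    "composite_motor",
)

#: At-risk subtype labels, cycled in the cohort's observed 6:4:1 mix.
AR_SUBTYPES = (
    ("AR_preterm_high", 6),
    ("AR_preterm_low", 4),
    ("AR_fullterm_high", 1),
)


@dataclass(frozen=True)
class ChannelProfile:
    """Ground-truth spectral parameters for one channel."""

    peak_freq_hz: float
    peak_amp_uv: float
    phase_rad: float = 0.0
    bg_amp_uv: float = 15.0
    bg_exponent: float = 1.5
    noise_sd_uv: float = 2.0


def default_bayley_coefficients() -> Dict[str, Tuple[float, float, float, float]]:
    """Per-outcome (intercept, beta_age, beta_group, beta_vrp) defaults.

    Raw subscale scores rise roughly linearly over the first months; the
    group effect is zero by default so that any group signal flows through
    the VRP term.  beta_vrp is negative (more spectral heterogeneity,
    lower developmental score) and sized against the generator's typical
    VRP spread of a few hundredths.  Composite scores are on the
    mean-100/SD-15 scale.
    """
    return {
        "bayley_raw_fine_motor": (8.0, 0.10, 0.0, -250.0),
        "bayley_raw_gross_motor": (6.0, 0.12, 0.0, -80.0),
        "bayley_raw_receptive_lang": (5.0, 0.06, 0.0, -30.0),
        "bayley_raw_expressive_lang": (4.0, 0.05, 0.0, -30.0),
        "bayley_raw_cognitive": (10.0, 0.14, 0.0, -250.0),
        "composite_cognitive": (103.0, 0.0, 0.0, -300.0),
        "composite_language": (101.0, 0.0, 0.0, -150.0),
        "composite_motor": (104.0, 0.0, 0.0, -450.0),
    }


def default_bayley_noise_sd() -> Dict[str, float]:
    return {
        "bayley_raw_fine_motor": 2.0,
        "bayley_raw_gross_motor": 2.5,
        "bayley_raw_receptive_lang": 1.5,
        "bayley_raw_expressive_lang": 1.5,
        "bayley_raw_cognitive": 2.5,
        "composite_cognitive": 8.0,
        "composite_language": 8.0,
        "composite_motor": 8.0,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with cohort-matched defaults."""

    n_td: int = 22
    n_ar: int = 11
    age_range_td_days: Tuple[int, int] = (38, 203)
    age_range_ar_days: Tuple[int, int] = (40, 225)
    fs_hz: float = 512.0
    n_channels: int = 32
    duration_range_s: Tuple[float, float] = (20.0, 82.0)
    heterogeneity_td: float = 0.2
    heterogeneity_ar: float = 0.35
    visit_stability: float = 0.7
    center_freq_hz: float = 6.0
    peak_amp_uv: float = 10.0
    bg_amp_uv: float = 15.0
    background_exponent: float = 1.5
    noise_sd_uv: float = 2.0
    artifact_rate_per_min: float = 2.0
    bayley_coefficients: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=default_bayley_coefficients
    )
    bayley_noise_sd: object = field(default_factory=default_bayley_noise_sd)
    visit3_n_td: int = 13
    visit3_n_ar: int = 9
    visit_interval_days: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_td < 1 or self.n_ar < 1:
            raise ValueError("group sizes must be >= 1")
        if self.heterogeneity_td < 0 or self.heterogeneity_ar < 0:
            raise ValueError("heterogeneity parameters must be nonnegative")
        if not self.fs_hz > 2 * 30.0:
            raise ValueError("fs_hz must exceed twice the 30 Hz analysis band")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("duration_range_s must be positive and ordered")
        if self.center_freq_hz >= self.fs_hz / 2:
            raise ValueError("oscillation frequency must be below Nyquist")
        if isinstance(self.bayley_noise_sd, (int, float)):
            self.bayley_noise_sd = {
                k: float(self.bayley_noise_sd) for k in self.bayley_coefficients
            }
        for name, coefs in self.bayley_coefficients.items():
            if not np.all(np.isfinite(coefs)):
                raise ValueError(f"non-finite Bayley coefficients for {name!r}")
        if self.visit3_n_td > self.n_td or self.visit3_n_ar > self.n_ar:
            raise ValueError("visit-3 counts cannot exceed group sizes")

    def channel_labels(self) -> Tuple[str, ...]:
        if self.n_channels == 32:
            return CHANNELS_32
        return tuple(f"CH{i + 1}" for i in range(self.n_channels))


@dataclass
class GeneratedCohort:
    """Recordings (possibly empty), cohort table, and the ground truth."""

    recordings: Dict[Tuple[str, int], MultichannelRecording]
    cohort: pd.DataFrame
    ground_truth: dict


def draw_channel_profiles(
    rng: np.random.Generator,
    n_channels: int,
    center_freq_hz: float,
    sigma_h: float,
    peak_amp_uv: float,
    bg_amp_uv: float,
    bg_exponent: float,
    noise_sd_uv: float,
    min_freq_hz: float = 1.0,
    max_freq_hz: float = 25.0,
    z_freq: Optional[np.ndarray] = None,
    z_amp: Optional[np.ndarray] = None,
) -> list[ChannelProfile]:
    """Jitter each channel's peak frequency (Hz) and log-amplitude by
    N(0, sigma_h^2) around the group means; clip frequency to the band.

    ``z_freq``/``z_amp`` optionally supply the standard-normal jitter
    directly (used to correlate a subject's profiles across visits).
    """
    if z_freq is None:
        z_freq = rng.standard_normal(n_channels)
    if z_amp is None:
        z_amp = rng.standard_normal(n_channels)
    freqs = np.clip(center_freq_hz + sigma_h * z_freq, min_freq_hz, max_freq_hz)
    amps = peak_amp_uv * np.exp(sigma_h * z_amp)
    phases = rng.uniform(0, 2 * math.pi, n_channels)
    return [
        ChannelProfile(
            peak_freq_hz=float(f),
            peak_amp_uv=float(a),
            phase_rad=float(p),
            bg_amp_uv=bg_amp_uv,
            bg_exponent=bg_exponent,
            noise_sd_uv=noise_sd_uv,
        )
        for f, a, p in zip(freqs, amps, phases)
    ]


def _one_over_f_background(
    rng: np.random.Generator,
    n_samples: int,
    fs_hz: float,
    amp_uv: float,
    exponent: float,
) -> np.ndarray:
    """Gaussian noise with one-sided PSD K * f^-alpha, scaled to SD amp_uv.

    Synthesized in the frequency domain: each rfft bin gets a complex
    Gaussian with |Z_k|^2 = S_k * fs * n / 2 in expectation, which makes
    the periodogram an unbiased estimate of the target density S.
    """
    if amp_uv == 0:
        return np.zeros(n_samples)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent)
    df = fs_hz / n_samples
    total = shape.sum() * df  # integral of f^-alpha over the grid
    s_density = (amp_uv**2 / total) * shape
    scale = np.sqrt(s_density * fs_hz * n_samples / 2.0)
    z = scale * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    ) / math.sqrt(2.0)
    z[0] = 0.0
    if n_samples % 2 == 0:
        z[-1] = z[-1].real * math.sqrt(2.0)
    return np.fft.irfft(z, n=n_samples)


def generate_recording(
    channel_profiles: list[ChannelProfile],
    duration_s: float,
    fs_hz: float,
    artifact_rate_per_min: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    subject_id: Optional[str] = None,
    visit: Optional[int] = None,
    channel_labels: Optional[Tuple[str, ...]] = None,
    artifact_amp_factor: float = 10.0,
    artifact_duration_s: float = 0.5,
) -> MultichannelRecording:
    """Render one session: background + oscillation + noise + artifacts.

    Artifact bursts are rectangular offsets of ``artifact_amp_factor``
    times the clean signal's standard deviation, lasting
    ``artifact_duration_s``, applied to every channel, with Poisson
    arrivals at ``artifact_rate_per_min`` per minute — deliberately
    unambiguous for an absolute-amplitude rejection rule.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    nyq = fs_hz / 2.0
    for i, prof in enumerate(channel_profiles):
        if prof.peak_freq_hz >= nyq:
            raise ValueError(
                f"channel {i}: oscillation frequency {prof.peak_freq_hz} Hz "
                f"is at or above Nyquist ({nyq} Hz)"
            )
    n_ch = len(channel_profiles)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    x = np.empty((n_ch, n))
    for i, prof in enumerate(channel_profiles):
        sig = prof.peak_amp_uv * np.sin(
            2 * math.pi * prof.peak_freq_hz * t + prof.phase_rad
        )
        sig = sig + _one_over_f_background(
            rng, n, fs_hz, prof.bg_amp_uv, prof.bg_exponent
        )
        if prof.noise_sd_uv > 0:
            sig = sig + prof.noise_sd_uv * rng.standard_normal(n)
        x[i] = sig
    if artifact_rate_per_min > 0:
        n_bursts = rng.poisson(artifact_rate_per_min * duration_s / 60.0)
        if n_bursts:
            burst_amp = artifact_amp_factor * x.std()
            burst_len = int(round(artifact_duration_s * fs_hz))
            starts = rng.uniform(0, max(duration_s - artifact_duration_s, 0), n_bursts)
            for s in starts:
                i0 = int(s * fs_hz)
                x[:, i0 : i0 + burst_len] += burst_amp
    if channel_labels is None:
        channel_labels = (
            CHANNELS_32 if n_ch == 32 else tuple(f"CH{i + 1}" for i in range(n_ch))
        )
    return MultichannelRecording(
        samples=x,
        channel_labels=channel_labels,
        fs_hz=fs_hz,
        subject_id=subject_id,
        visit=visit,
    )


def expected_peak_relative_power(
    peak_freq_hz: np.ndarray,
    peak_amp_uv: np.ndarray,
    bg_amp_uv: float,
    bg_exponent: float,
    noise_sd_uv: float,
    fs_hz: float = 512.0,
    segment_s: float = 2.0,
    fmin: float = 0.0,
    fmax: float = 30.0,
) -> np.ndarray:
    """Noise-free theoretical peak relative power per channel.

    Builds the analytic PSD of the generator model on the Welch bin grid
    (background density K f^-alpha, flat sensor-noise density, the
    sinusoid's A^2/2 power dropped into its nearest bin), normalizes over
    [fmin, fmax] and takes the per-channel max.  Broadcasts over leading
    axes of ``peak_freq_hz`` / ``peak_amp_uv``.
    """
    peak_freq_hz = np.asarray(peak_freq_hz, dtype=float)
    peak_amp_uv = np.asarray(peak_amp_uv, dtype=float)
    df = 1.0 / segment_s
    freqs = np.arange(0.0, fs_hz / 2.0 + df / 2, df)
    band = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    fband = freqs[band]

    bg = np.zeros_like(fband)
    if bg_amp_uv > 0:
        # same normalization grid idea as the generator: density K f^-alpha
        pos = fband > 0
        shape = np.zeros_like(fband)
        shape[pos] = fband[pos] ** (-bg_exponent)
        full_pos = freqs[freqs > 0]
        total = (full_pos ** (-bg_exponent)).sum() * df
        bg = (bg_amp_uv**2 / total) * shape
    noise_density = (
        noise_sd_uv**2 / (fs_hz / 2.0) if noise_sd_uv > 0 else 0.0
    )
    base = bg + noise_density  # (n_bins,)

    psd = np.broadcast_to(
        base, peak_freq_hz.shape + (fband.size,)
    ).copy()
    idx = np.clip(np.round((peak_freq_hz - fband[0]) / df).astype(int), 0, fband.size - 1)
    sin_power_density = (peak_amp_uv**2 / 2.0) / df
    np.put_along_axis(
        psd,
        idx[..., None],
        np.take_along_axis(psd, idx[..., None], axis=-1)
        + sin_power_density[..., None],
        axis=-1,
    )
    rp = psd / psd.sum(axis=-1, keepdims=True)
    return rp.max(axis=-1)


def expected_vrp(
    peak_freq_hz: np.ndarray,
    peak_amp_uv: np.ndarray,
    bg_amp_uv: float,
    bg_exponent: float,
    noise_sd_uv: float,
    fs_hz: float = 512.0,
    segment_s: float = 2.0,
) -> np.ndarray:
    """SD across channels (last axis) of the theoretical peak relative power."""
    peaks = expected_peak_relative_power(
        peak_freq_hz, peak_amp_uv, bg_amp_uv, bg_exponent, noise_sd_uv,
        fs_hz=fs_hz, segment_s=segment_s,
    )
    return np.std(peaks, ddof=1, axis=-1)


def _subject_ids(config: SimulationConfig) -> Tuple[list, list]:
    td = [f"TD{i + 1:02d}" for i in range(config.n_td)]
    ar = [f"AR{i + 1:02d}" for i in range(config.n_ar)]
    return td, ar


def _ar_subtype(i: int) -> str:
    cycle = []
    for name, count in AR_SUBTYPES:
        cycle.extend([name] * count)
    return cycle[i % len(cycle)]


def generate_cohort(
    config: SimulationConfig, render_eeg: bool = True
) -> GeneratedCohort:
    """Draw the full synthetic study.

    Per session a fresh set of channel profiles is drawn with the group's
    heterogeneity; the session's ground-truth expected VRP enters the
    Bayley linear model.  With ``render_eeg=False`` only the cohort table
    and ground truth are produced (fast path for Monte-Carlo calibration
    of the inference layer).
    """
    rng = np.random.default_rng(config.seed)
    td_ids, ar_ids = _subject_ids(config)
    labels = config.channel_labels()

    subjects = [(sid, "TD") for sid in td_ids] + [
        (sid, _ar_subtype(i)) for i, sid in enumerate(ar_ids)
    ]
    v1_ages = {}
    for sid, group in subjects:
        lo, hi = (
            config.age_range_td_days if group == "TD" else config.age_range_ar_days
        )
        v1_ages[sid] = int(rng.integers(lo, hi + 1))
    # which subjects return for visit 3
    back_td = set(rng.choice(td_ids, size=config.visit3_n_td, replace=False))
    back_ar = set(rng.choice(ar_ids, size=config.visit3_n_ar, replace=False))
    returning = back_td | back_ar

    sessions = []  # (sid, group, visit, age)
    for sid, group in subjects:
        sessions.append((sid, group, 1, v1_ages[sid]))
    for sid, group in subjects:
        if sid in returning:
            sessions.append(
                (sid, group, 3, v1_ages[sid] + config.visit_interval_days)
            )

    # per-subject spectral "trait": the part of the channel jitter that is
    # stable across visits (correlation visit_stability between visits)
    traits = {
        sid: (
            rng.standard_normal(config.n_channels),
            rng.standard_normal(config.n_channels),
        )
        for sid, _ in subjects
    }
    rho = float(np.clip(config.visit_stability, 0.0, 1.0))

    recordings: Dict[Tuple[str, int], MultichannelRecording] = {}
    rows = []
    gt_profiles = {}
    for sid, group, visit, age in sessions:
        sigma_h = (
            config.heterogeneity_td if group == "TD" else config.heterogeneity_ar
        )
        tf, ta = traits[sid]
        z_f = math.sqrt(rho) * tf + math.sqrt(1 - rho) * rng.standard_normal(
            config.n_channels
        )
        z_a = math.sqrt(rho) * ta + math.sqrt(1 - rho) * rng.standard_normal(
            config.n_channels
        )
        profiles = draw_channel_profiles(
            rng,
            config.n_channels,
            config.center_freq_hz,
            sigma_h,
            config.peak_amp_uv,
            config.bg_amp_uv,
            config.background_exponent,
            config.noise_sd_uv,
            z_freq=z_f,
            z_amp=z_a,
        )
        gt_profiles[(sid, visit)] = profiles
        true_vrp = float(
            expected_vrp(
                np.array([p.peak_freq_hz for p in profiles]),
                np.array([p.peak_amp_uv for p in profiles]),
                config.bg_amp_uv,
                config.background_exponent,
                config.noise_sd_uv,
                fs_hz=config.fs_hz,
            )
        )
        at_risk = int(group != "TD")
        row = {
            "subject_id": sid,
            "group": group,
            "visit": visit,
            "age_days_adjusted": age,
            "at_risk": at_risk,
            "vrp_true": true_vrp,
        }
        for name, (b0, b_age, b_grp, b_vrp) in config.bayley_coefficients.items():
            sd = config.bayley_noise_sd[name]
            val = (
                b0
                + b_age * age
                + b_grp * at_risk
                + b_vrp * true_vrp
                + (sd * rng.standard_normal() if sd > 0 else 0.0)
            )
            row[name] = val
        present_raw = [k for k in RAW_OUTCOMES if k in row]
        if present_raw:
            row["bayley_total_raw"] = sum(row[k] for k in present_raw)
        for comp in (c for c in COMPOSITE_OUTCOMES if c in row):
            row[comp] = float(np.clip(row[comp], 40.0, 160.0))
            pct = 100.0 * stats.norm.cdf((row[comp] - 100.0) / 15.0)
            row[comp.replace("composite_", "percentile_")] = float(
                np.clip(pct, 0.1, 99.9)
            )
        rows.append(row)

        if render_eeg:
            duration = rng.uniform(*config.duration_range_s)
            recordings[(sid, visit)] = generate_recording(
                profiles,
                duration_s=duration,
                fs_hz=config.fs_hz,
                artifact_rate_per_min=config.artifact_rate_per_min,
                rng=rng,
                subject_id=sid,
                visit=visit,
                channel_labels=labels,
            )

    cohort = pd.DataFrame(rows)
    ground_truth = {
        "profiles": gt_profiles,
        "coefficients": dict(config.bayley_coefficients),
        "config": config,
    }
    return GeneratedCohort(
        recordings=recordings, cohort=cohort, ground_truth=ground_truth
    )
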