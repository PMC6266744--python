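"""File I/O: recordings (CSV matrix + label sidecar, EDF read), cohort
tables, feature tables, and the precomputed relative-power spreadsheet
dialect.

On-disk recording format: ``<stem>.csv`` holds the channels x samples
matrix (one row per channel, no header) and ``<stem>.labels.json`` holds
``{"channel_labels": [...], "fs_hz": ..., "subject_id": ..., "visit": ...,
"units": "uV"}``.  EDF files are read through :mod:`mne` when it is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import MultichannelRecording, SessionFeature

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "read_recording_edf",
    "read_recording",
    "write_cohort_csv",
    "read_cohort_csv",
    "features_to_frame",
    "read_precomputed_relative_power",
]

COHORT_REQUIRED = ("subject_id", "group", "visit", "age_days_adjusted")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix("").with_suffix(".labels.json")


def write_recording_csv(rec: MultichannelRecording, path) -> Path:
    """Write channels x samples CSV plus the labels sidecar; returns path."""
    path = Path(path)
    np.savetxt(path, rec.samples, delimiter=",", fmt="%.6g")
    meta = {
        "channel_labels": list(rec.channel_labels),
        "fs_hz": rec.fs_hz,
        "subject_id": rec.subject_id,
        "visit": rec.visit,
        "units": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording_csv(path, scale_to_uv: float = 1.0) -> MultichannelRecording:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    samples = np.loadtxt(path, delimiter=",", ndmin=2) * scale_to_uv
    return MultichannelRecording(
        samples=samples,
        channel_labels=tuple(meta["channel_labels"]),
        fs_hz=float(meta["fs_hz"]),
        subject_id=meta.get("subject_id"),
        visit=meta.get("visit"),
    )


def read_recording_edf(
    path, subject_id: Optional[str] = None, visit: Optional[int] = None
) -> MultichannelRecording:
    """Read an EDF recording via MNE; samples are converted to microvolts."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install eegvrp[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return MultichannelRecording(
        samples=raw.get_data() * 1e6,  # MNE loads EEG in volts
        channel_labels=tuple(raw.ch_names),
        fs_hz=float(raw.info["sfreq"]),
        subject_id=subject_id,
        visit=visit,
    )


def read_recording(path, **kw) -> MultichannelRecording:
    """Dispatch on extension: .edf via MNE, .csv via the sidecar dialect."""
    p = Path(path)
    if p.suffix.lower() == ".edf":
        return read_recording_edf(p, **kw)
    return read_recording_csv(p, **kw)


def write_cohort_csv(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    if "at_risk" not in df.columns:
        df["at_risk"] = (df["group"] != "TD").astype(int)
    if (df["age_days_adjusted"] <= 0).any():
        raise ValueError("ages must be positive")
    for col in ("composite_cognitive", "composite_language", "composite_motor"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 40) | (vals > 160)).any():
                raise ValueError(f"{col} outside the 40-160 composite range")
    return df


def features_to_frame(features: Sequence[SessionFeature]) -> pd.DataFrame:
    """Per-session feature rows: vrp, provenance, 32 electrode summaries."""
    rows = []
    for f in features:
        row = {
            "subject_id": f.subject_id,
            "visit": f.visit,
            "vrp": f.vrp,
            "summary_mode": f.summary_mode,
            "retained_duration_s": f.retained_duration_s,
            "n_epochs_total": f.n_epochs_total,
            "n_epochs_retained": f.n_epochs_retained,
        }
        for i, v in enumerate(f.per_electrode_summary):
            row[f"electrode_{i + 1:02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def read_precomputed_relative_power(
    path,
    electrode_columns: Optional[Sequence[str]] = None,
    subject_col: str = "subject_id",
    visit_col: str = "visit",
    column_map: Optional[dict] = None,
) -> pd.DataFrame:
    """Read a wide per-session relative-power spreadsheet and compute VRP.

    Expected layout: one row per session, one column per electrode holding
    that electrode's relative-power summary (peak relative power), plus
    subject/visit identifier columns.  ``column_map`` renames dialect
    columns first; ``electrode_columns`` selects the electrode columns
    explicitly (default: every numeric column that is not an identifier).
    VRP is the sample SD (n-1) across the electrode columns.
    """
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(p)
    else:
        df = pd.read_csv(p)
    if column_map:
        df = df.rename(columns=column_map)
    for col in (subject_col, visit_col):
        if col not in df.columns:
            raise ValueError(f"missing identifier column {col!r}")
    if electrode_columns is None:
        electrode_columns = [
            c
            for c in df.columns
            if c not in (subject_col, visit_col)
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    if len(electrode_columns) < 2:
        raise ValueError("need >= 2 electrode columns to compute a VRP")
    vals = df[list(electrode_columns)].to_numpy(dtype=float)
    out = df[[subject_col, visit_col]].copy()
    out.columns = ["subject_id", "visit"]
    out["vrp"] = vals.std(ddof=1, axis=1)
    for c in electrode_columns:
        out[c] = df[c].to_numpy(dtype=float)
    return out
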