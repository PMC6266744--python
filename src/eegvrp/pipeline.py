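"""End-to-end orchestration: simulate/load -> preprocess -> VRP features ->
classification and developmental-score models, with a reproducible run
manifest.

``run_pipeline`` executes the enabled stages in order and writes:

* ``features.csv`` — per-session VRP + provenance + electrode summaries
* ``classification_report.json`` / ``.csv`` — LRT, odds ratio, LOOCV
  confusion matrix on visit-1 data
* ``bayley_models.csv`` — the 12-outcome null/full model comparison table
* ``future_prediction.json`` — the visit-1 -> visit-3 nested comparison
* ``manifest.json`` — config echo + hash, seed, software version and
  per-session retained durations

Identical config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, io
from .inference import (
    fit_logistic_lrt,
    loocv_confusion,
    predict_future_visit,
    same_visit_table,
)
from .simulate import SimulationConfig, generate_cohort
from .spectral import VRPTransformer

__all__ = ["PipelineConfig", "run_pipeline"]

INPUT_MODES = ("synthetic", "recordings", "precomputed")


@dataclass
class PipelineConfig:
    """Every stage parameter of one pipeline run.

    Unknown keys are rejected by :meth:`from_dict`, and the full config is
    echoed verbatim into the run manifest.
    """

    input_mode: str = "synthetic"
    out_dir: str = "eegvrp_run"
    seed: int = 0
    # synthetic mode
    simulation: dict = field(default_factory=dict)
    write_recordings: bool = False
    # recordings / precomputed modes
    cohort_csv: Optional[str] = None
    recordings_dir: Optional[str] = None
    relative_power_csv: Optional[str] = None
    relative_power_column_map: Optional[dict] = None
    # preprocessing + spectral parameters
    low_hz: float = 0.3
    high_hz: float = 30.0
    epoch_length_s: float = 2.0
    amplitude_threshold_uv: float = 200.0
    segment_s: float = 2.0
    overlap_frac: float = 0.5
    fmin: float = 0.0
    fmax: float = 30.0
    summary_mode: str = "peak"
    # inference parameters
    loocv_threshold: float = 0.5
    null_includes_risk: bool = True
    future_outcome: str = "bayley_raw_fine_motor"
    # sessions retaining less than min_retained_s are flagged; strict mode
    # excludes them from the analysis
    min_retained_s: float = 14.0
    strict_min_duration: bool = False

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(
                f"input_mode must be one of {INPUT_MODES}, got {self.input_mode!r}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _feature_table(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Returns (features frame, cohort frame, extra-manifest dict)."""
    extra: dict = {}
    if cfg.input_mode == "synthetic":
        sim = SimulationConfig(**{**cfg.simulation, "seed": cfg.seed})
        gen = generate_cohort(sim, render_eeg=True)
        cohort = gen.cohort
        tf = VRPTransformer(
            low_hz=cfg.low_hz,
            high_hz=cfg.high_hz,
            epoch_length_s=cfg.epoch_length_s,
            amplitude_threshold_uv=cfg.amplitude_threshold_uv,
            segment_s=cfg.segment_s,
            overlap_frac=cfg.overlap_frac,
            fmin=cfg.fmin,
            fmax=cfg.fmax,
            summary_mode=cfg.summary_mode,
        )
        recs = [gen.recordings[k] for k in sorted(gen.recordings)]
        feats = io.features_to_frame(tf.transform_sessions(recs))
        if cfg.write_recordings:
            rec_dir = Path(cfg.out_dir) / "recordings"
            rec_dir.mkdir(parents=True, exist_ok=True)
            for (sid, visit), rec in sorted(gen.recordings.items()):
                io.write_recording_csv(rec, rec_dir / f"{sid}_v{visit}.csv")
        return feats, cohort, extra
    if cfg.input_mode == "recordings":
        if not (cfg.cohort_csv and cfg.recordings_dir):
            raise ValueError(
                "recordings mode needs cohort_csv and recordings_dir"
            )
        cohort = io.read_cohort_csv(cfg.cohort_csv)
        tf = VRPTransformer(
            low_hz=cfg.low_hz,
            high_hz=cfg.high_hz,
            epoch_length_s=cfg.epoch_length_s,
            amplitude_threshold_uv=cfg.amplitude_threshold_uv,
            segment_s=cfg.segment_s,
            overlap_frac=cfg.overlap_frac,
            fmin=cfg.fmin,
            fmax=cfg.fmax,
            summary_mode=cfg.summary_mode,
        )
        recs = []
        rec_dir = Path(cfg.recordings_dir)
        for _, row in cohort.iterrows():
            stem = f"{row.subject_id}_v{row.visit}"
            for ext in (".csv", ".edf"):
                p = rec_dir / (stem + ext)
                if p.exists():
                    rec = io.read_recording(p)
                    rec.subject_id = row.subject_id
                    rec.visit = int(row.visit)
                    recs.append(rec)
                    break
            else:
                raise FileNotFoundError(
                    f"no recording found for session {stem} in {rec_dir}"
                )
        feats = io.features_to_frame(tf.transform_sessions(recs))
        return feats, cohort, extra
    # precomputed relative-power mode
    if not (cfg.cohort_csv and cfg.relative_power_csv):
        raise ValueError(
            "precomputed mode needs cohort_csv and relative_power_csv"
        )
    cohort = io.read_cohort_csv(cfg.cohort_csv)
    feats = io.read_precomputed_relative_power(
        cfg.relative_power_csv, column_map=cfg.relative_power_column_map
    )
    extra["relative_power_source"] = str(cfg.relative_power_csv)
    return feats, cohort, extra


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    feats, cohort, extra = _feature_table(cfg)
    feats = feats.sort_values(["subject_id", "visit"]).reset_index(drop=True)
    if "retained_duration_s" in feats.columns:
        feats["below_min_retained"] = (
            feats["retained_duration_s"] < cfg.min_retained_s
        )
        if cfg.strict_min_duration:
            feats = feats[~feats["below_min_retained"]].reset_index(drop=True)
    feats.to_csv(out / "features.csv", index=False)

    table = cohort.merge(
        feats[["subject_id", "visit", "vrp"]], on=["subject_id", "visit"], how="inner"
    )
    if "at_risk" not in table.columns:
        table["at_risk"] = (table["group"] != "TD").astype(int)

    # --- classification on visit 1 ---
    v1 = table[table["visit"] == 1]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        logit = fit_logistic_lrt(v1["vrp"], v1["at_risk"])
        conf = loocv_confusion(v1["vrp"], v1["at_risk"], threshold=cfg.loocv_threshold)
    notes = sorted({str(w.message) for w in caught})
    classification = {
        "n": logit.n,
        "lrt_chi2": logit.lrt_chi2,
        "lrt_df": logit.df,
        "lrt_p": logit.p_value,
        "odds_ratio": logit.odds_ratio if math.isfinite(logit.odds_ratio) else None,
        "odds_ratio_per_sd": logit.odds_ratio_per_sd,
        "feature_sd": logit.feature_sd,
        "slope": logit.slope,
        "intercept": logit.intercept,
        "feature_scale": logit.feature_scale,
        "degenerate": logit.degenerate,
        "separation": logit.separation,
        "loocv": {
            "threshold": cfg.loocv_threshold,
            "tp": conf.tp,
            "tn": conf.tn,
            "fp": conf.fp,
            "fn": conf.fn,
            "accuracy": conf.accuracy,
            "sensitivity": conf.sensitivity,
            "specificity": conf.specificity,
        },
        "warnings": notes,
    }
    _json_dump(classification, out / "classification_report.json")
    pd.DataFrame(
        [
            {
                "lrt_chi2": logit.lrt_chi2,
                "lrt_df": logit.df,
                "lrt_p": logit.p_value,
                "odds_ratio": logit.odds_ratio,
                "accuracy": conf.accuracy,
                "sensitivity": conf.sensitivity,
                "specificity": conf.specificity,
            }
        ]
    ).to_csv(out / "classification_report.csv", index=False)

    # --- same-visit developmental-score models ---
    available = [
        c
        for c in (
            "bayley_raw_fine_motor",
            "bayley_raw_gross_motor",
            "bayley_raw_receptive_lang",
            "bayley_raw_expressive_lang",
            "bayley_raw_cognitive",
            "bayley_total_raw",
            "composite_cognitive",
            "percentile_cognitive",
            "composite_language",
            "percentile_language",
            "composite_motor",
            "percentile_motor",
        )
        if c in table.columns
    ]
    bayley = same_visit_table(
        table, outcomes=available, null_includes_risk=cfg.null_includes_risk
    )
    bayley.to_csv(out / "bayley_models.csv", index=False)

    # --- future-visit prediction ---
    future = None
    if (table["visit"] == 3).any() and cfg.future_outcome in table.columns:
        try:
            mc = predict_future_visit(table, outcome=cfg.future_outcome)
            future = {
                "outcome": mc.outcome,
                "n_linked": mc.full_fit.n,
                "adj_r2_null": mc.null_fit.adj_r2,
                "adj_r2_full": mc.full_fit.adj_r2,
                "delta_adj_r2": mc.delta_adj_r2,
                "partial_f": mc.partial_f,
                "anova_p": mc.anova_p,
            }
        except ValueError as exc:
            future = {"skipped": str(exc)}
    if future is not None:
        _json_dump(future, out / "future_prediction.json")

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "software_version": __version__,
        "n_sessions": int(len(feats)),
        "retained_durations_s": (
            {
                f"{r.subject_id}_v{r.visit}": r.retained_duration_s
                for r in feats.itertuples()
            }
            if "retained_duration_s" in feats.columns
            else None
        ),
        **extra,
    }
    _json_dump(manifest, out / "manifest.json")
    return manifest
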