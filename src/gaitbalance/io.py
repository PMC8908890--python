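"""File formats, run configuration and the end-to-end pipeline.

Recordings travel as plain CSV (one row per 60 Hz sample, SI units, header
mandatory); configuration as YAML.  ``run_pipeline`` sequences detection,
segmentation, identification and evaluation and emits a machine-readable
report that includes every effective default, so a run can be reproduced
from its report alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .anthropometry import build_subject_model
from .gait_phase import (
    DetectorThresholds,
    PhaseTimeline,
    bout_cycle_statistics,
    detect_phases,
)
from .identification import fit_controller, model_zmp_trace, segment_trials, to_local_frame
from .recording import GaitRecording, resample

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "write_recording",
    "write_timelines",
    "read_timelines",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


def read_recording(path, resample_hz: float | None = None) -> GaitRecording:
    """Read a recording CSV; optionally resample to a uniform grid."""
    df = pd.read_csv(path)
    rec = GaitRecording(df)
    if resample_hz:
        rec = resample(rec, resample_hz)
    return rec


def write_recording(recording: GaitRecording, path) -> None:
    """Write a recording CSV; round trips are lossless to 1e-12."""
    recording.data.to_csv(path, index=False, float_format="%.17g")


def write_timelines(timelines: dict, path) -> None:
    rows = []
    for leg, tl in timelines.items():
        for t0, t1, phase in tl.intervals():
            rows.append({"leg": leg, "phase": phase, "t_start": t0, "t_end": t1})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_timelines(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for leg, g in df.groupby("leg"):
        g = g.sort_values("t_start", kind="stable")
        entries = [(float(r.t_start), str(r.phase)) for r in g.itertuples()]
        out[str(leg)] = PhaseTimeline(leg=str(leg), entries=entries, end_time=float(g["t_end"].max()))
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-serializable)."""

    height_m: float = 1.65
    mass_kg: float = 57.0
    segment_overrides: dict | None = None
    thresholds: DetectorThresholds = field(default_factory=DetectorThresholds)
    constraint_product: float | None = None
    frame: str = "global"
    seed: int = 0
    sample_rate: float = 60.0
    n_starts: int = 8

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.frame not in ("global", "local"):
            raise ValueError("frame must be 'global' or 'local'")
        if isinstance(self.thresholds, dict):
            self.thresholds = DetectorThresholds(**self.thresholds)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    subject = raw.pop("subject", {})
    cfg = RunConfig(
        height_m=subject.get("height_m", 1.65),
        mass_kg=subject.get("mass_kg", 57.0),
        segment_overrides=subject.get("segments"),
        thresholds=raw.get("thresholds", {}),
        constraint_product=raw.get("controller", {}).get("constraint_product"),
        frame=raw.get("frame", "global"),
        seed=raw.get("seed", 0),
        sample_rate=raw.get("sample_rate", 60.0),
        n_starts=raw.get("controller", {}).get("n_starts", 8),
    )
    return cfg


def run_pipeline(config: RunConfig, recording: GaitRecording) -> dict:
    """Detect -> segment -> identify -> evaluate; returns the report dict."""
    report: dict = {"config": config.to_dict(), "stages": []}
    subject = build_subject_model(config.height_m, config.mass_kg, config.segment_overrides)
    rec = recording

    def stage(name, fn):
        try:
            out = fn()
        except Exception as exc:  # re-raise with the stage name attached
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        report["stages"].append(name)
        return out

    if config.frame == "local":
        rec = stage("local_frame", lambda: to_local_frame(rec))
    timelines = stage("detect", lambda: detect_phases(rec, subject, config.thresholds))
    stats = stage("statistics", lambda: bout_cycle_statistics(timelines))
    segments = stage("segment", lambda: segment_trials(timelines))
    result = stage(
        "identify",
        lambda: fit_controller(
            rec,
            segments,
            constraint_product=config.constraint_product,
            n_starts=config.n_starts,
            seed=config.seed,
        ),
    )
    trace = stage("evaluate", lambda: model_zmp_trace(result, rec, segments))
    report["phases"] = {
        leg: [
            {"t_start": t0, "t_end": t1, "phase": p} for t0, t1, p in tl.intervals()
        ]
        for leg, tl in timelines.items()
    }
    report["statistics"] = {
        "stance_pct": stats["stance_pct"],
        "swing_pct": stats["swing_pct"],
        "per_leg": {
            leg: (
                {"n_cycles": s["n_cycles"], "phase_pct": s["phase_pct"], "stance_pct": s["stance_pct"]}
                if s
                else None
            )
            for leg, s in stats["per_leg"].items()
        },
    }
    report["fit"] = {
        "zeta1": result.zeta1,
        "zeta2": result.zeta2,
        "zeta_product": result.zeta1 * result.zeta2,
        "x_p": list(result.x_p),
        "x_sd": {str(k): v for k, v in result.x_sd.items()},
        "rmse_m": result.rmse,
        "converged": result.converged,
        "n_samples": result.n_samples,
    }
    report["evaluation"] = {"rmse_m": trace["rmse"]}
    logger.info(
        "pipeline done: zeta1=%.3f zeta2=%.3f rmse=%.4f m", result.zeta1, result.zeta2, result.rmse
    )
    return report
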