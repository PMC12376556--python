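"""End-to-end pipeline: (simulate | load) → classify → metrics → density → report.

A :class:`PipelineConfig` names exactly one input source — a track-table
file (with its acquisition metadata) or a :class:`SimulationParams` — plus
the spheroid geometry and the rM displacement threshold. ``run_pipeline``
writes, under the output directory:

* ``tracks.csv`` / ``truth.json``   (simulated input only)
* ``metrics.csv``   one row per (cell, segment) with d_total, disp,
  straightness, mean velocity and the rM label
* ``labels.json``   per-cell rM labels
* ``density.csv``   the pooled-location KDE grid
* ``summary.json``  cohort counts, per-segment velocity/straightness
  means ± SEM, and the group comparisons
* ``run.log``       config, seed and library versions

Re-running an identical config on simulated input reproduces every
numeric output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_reverse_migrated, cohort_segment_metrics
from .density import kde_heatmap, write_density_csv
from .errors import ParameterError, PipelineError
from .io import (
    ColumnDialect,
    read_tracks,
    validate_trackset,
    write_metadata,
    write_metrics_table,
    write_tracks,
)
from .simulate import GroundTruth, SimulationParams, simulate_trackset
from .stats import anova_oneway, group_comparison
from .tracks import SpheroidGeometry, TrackSet

log = logging.getLogger("rmtrack")


@dataclass
class PipelineConfig:
    """Everything one analysis run depends on. Exactly one input source."""

    tracks_path: Optional[str] = None
    pixel_size: Optional[float] = None  # required with tracks_path
    frame_interval: Optional[float] = None  # required with tracks_path
    dialect: ColumnDialect = field(default_factory=ColumnDialect)
    simulation: Optional[SimulationParams] = None
    spheroid: Optional[SpheroidGeometry] = None  # required with tracks_path
    min_reverse_displacement: float = 0.0
    density_segment: str = "all"  # all | approach | within | reverse
    density_points: str = "pooled"  # pooled | final
    output_dir: str = "rmtrack_out"
    seed: Optional[int] = None  # overrides simulation.seed when set
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.tracks_path is None) == (self.simulation is None):
            raise ParameterError(
                "exactly one input source required: tracks_path or simulation"
            )
        if self.tracks_path is not None:
            if self.pixel_size is None or self.frame_interval is None:
                raise ParameterError(
                    "pixel_size and frame_interval are required with tracks_path"
                )
            if self.spheroid is None:
                raise ParameterError("spheroid geometry is required with tracks_path")
        if self.density_segment not in ("all", "approach", "within", "reverse"):
            raise ParameterError(
                f"density_segment must be all|approach|within|reverse, "
                f"got {self.density_segment!r}"
            )
        if self.density_points not in ("pooled", "final"):
            raise ParameterError(
                f"density_points must be pooled|final, got {self.density_points!r}"
            )

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if raw.get("dialect"):
            raw["dialect"] = ColumnDialect(**raw["dialect"])
        if raw.get("spheroid"):
            raw["spheroid"] = SpheroidGeometry(**raw["spheroid"])
        if raw.get("simulation"):
            sim = dict(raw["simulation"])
            if sim.get("spheroid"):
                sim["spheroid"] = SpheroidGeometry(**sim["spheroid"])
            raw["simulation"] = SimulationParams(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    trackset: TrackSet
    truth: Optional[GroundTruth]
    metrics: pd.DataFrame
    labels: dict[str, bool]
    summary: dict
    output_dir: Path


def _mean_sem(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return {"n": 0, "mean": None, "sem": None}
    sem = float(np.std(values, ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return {"n": int(values.size), "mean": float(np.mean(values)), "sem": sem}


def _density_input(
    ts: TrackSet, metrics_cfg: PipelineConfig, spheroid: SpheroidGeometry
) -> np.ndarray:
    """Point cloud for the KDE, in spheroid-centered coordinates."""
    from .classify import segment_track
    from .kinematics import align_to_spheroid

    pts = []
    for t in ts.tracks:
        if len(t) == 0:
            continue
        at = align_to_spheroid(t, spheroid)
        if metrics_cfg.density_segment == "all":
            idx = np.arange(len(at))
        else:
            seg = segment_track(at, spheroid.radius,
                                metrics_cfg.min_reverse_displacement)
            idx = seg.indices(metrics_cfg.density_segment)
        if idx.size == 0:
            continue
        if metrics_cfg.density_points == "final":
            idx = idx[-1:]
        pts.append(np.column_stack([at.x[idx], at.y[idx]]))
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def build_summary(
    metrics: pd.DataFrame,
    labels: dict[str, bool],
    ts: TrackSet,
    truth: Optional[GroundTruth] = None,
) -> dict:
    """Cohort counts, per-segment kinematics and the group comparisons."""
    contacted = metrics.loc[metrics["segment"] == "within", "cell_id"].nunique()
    n_rm = int(sum(labels.values()))
    summary: dict = {
        "n_cells": len(ts),
        "n_contacted": int(contacted),
        "n_rm": n_rm,
        "segments": {},
        "comparisons": {},
    }
    for seg in ("approach", "within", "reverse", "whole"):
        sub = metrics[metrics["segment"] == seg]
        summary["segments"][seg] = {
            "mean_velocity": _mean_sem(sub["mean_velocity"].to_numpy()),
            "straightness": _mean_sem(sub["straightness"].to_numpy()),
        }

    def _vals(seg: str, col: str) -> np.ndarray:
        v = metrics.loc[metrics["segment"] == seg, col].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    pairs = [("approach", "within"), ("within", "reverse"), ("approach", "reverse")]
    for a, b in pairs:
        va, vb = _vals(a, "mean_velocity"), _vals(b, "mean_velocity")
        if va.size >= 2 and vb.size >= 2:
            summary["comparisons"][f"velocity_{a}_vs_{b}"] = group_comparison(
                va, vb, test="mann_whitney"
            ).as_dict()
    seg_vel = [_vals(s, "mean_velocity") for s in ("approach", "within", "reverse")]
    if all(v.size >= 2 for v in seg_vel):
        summary["comparisons"]["velocity_anova_segments"] = anova_oneway(*seg_vel)

    whole = metrics[metrics["segment"] == "whole"]
    rm_str = whole.loc[whole["rm_label"] == True, "straightness"].to_numpy(dtype=float)  # noqa: E712
    non_str = whole.loc[whole["rm_label"] == False, "straightness"].to_numpy(dtype=float)  # noqa: E712
    rm_str, non_str = rm_str[np.isfinite(rm_str)], non_str[np.isfinite(non_str)]
    if rm_str.size >= 2 and non_str.size >= 2:
        summary["comparisons"]["straightness_rm_vs_nonrm"] = group_comparison(
            rm_str, non_str, test="mann_whitney"
        ).as_dict()

    if truth is not None:
        true_labels = truth.rm_labels()
        agree = sum(labels[c] == true_labels[c] for c in labels)
        summary["ground_truth"] = {
            "n_rm_true": int(sum(true_labels.values())),
            "label_accuracy": agree / len(labels) if labels else None,
        }
    return summary


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    truth: Optional[GroundTruth] = None
    stage = "input"
    try:
        if config.simulation is not None:
            params = config.simulation
            if config.seed is not None:
                params = dataclasses.replace(params, seed=config.seed)
            ts, truth = simulate_trackset(params)
            write_tracks(ts, out / "tracks.csv")
            write_metadata(ts, out / "tracks.meta.json")
            truth.to_json(out / "truth.json")
            spheroid = params.spheroid
        else:
            ts = read_tracks(
                config.tracks_path,
                pixel_size=config.pixel_size,
                frame_interval=config.frame_interval,
                dialect=config.dialect,
            )
            ts.spheroid = spheroid = config.spheroid

        stage = "validation"
        errors = [v for v in validate_trackset(ts) if v.severity == "error"]
        if errors:
            cells = sorted({v.cell_id for v in errors if v.cell_id})
            raise PipelineError(
                f"stage {stage}: invalid trackset (cells {cells}): "
                + "; ".join(f"{v.cell_id}: {v.rule}" for v in errors[:5])
            )

        stage = "classification"
        labels = classify_reverse_migrated(
            ts, spheroid, config.min_reverse_displacement
        )
        (out / "labels.json").write_text(
            json.dumps(labels, indent=2, sort_keys=True) + "\n"
        )

        stage = "metrics"
        metrics = cohort_segment_metrics(
            ts, spheroid, ts.frame_interval, config.min_reverse_displacement
        )
        write_metrics_table(metrics, out / "metrics.csv")

        stage = "density"
        pts = _density_input(ts, config, spheroid)
        if pts.shape[0] >= 2:
            dg = kde_heatmap(pts)
            write_density_csv(dg, out / "density.csv")
        else:
            dg = None
            log.warning("density skipped: fewer than 2 points")

        stage = "report"
        summary = build_summary(metrics, labels, ts, truth)
        if dg is not None:
            summary["density"] = {
                "n_points": dg.n_points,
                "bandwidth_x": dg.bandwidth_x,
                "bandwidth_y": dg.bandwidth_y,
                "integral": dg.integral(),
            }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        _write_run_log(config, out / "run.log")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(f"stage {stage} failed: {e}") from e

    return PipelineResult(
        trackset=ts,
        truth=truth,
        metrics=metrics,
        labels=labels,
        summary=summary,
        output_dir=out,
    )


def _write_run_log(config: PipelineConfig, path: Path) -> None:
    import scipy

    lines = [
        f"rmtrack {__version__}",
        f"numpy {np.__version__}, scipy {scipy.__version__}, pandas {pd.__version__}",
        "config:",
        json.dumps(config.to_json_dict(), indent=2, sort_keys=True, default=str),
    ]
    path.write_text("\n".join(lines) + "\n")
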