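"""Reading, validating and writing delimited-text track tables.

Track tables are the flat per-row exports of manual/automatic cell
trackers: one row per (cell, frame) with pixel coordinates. Column names
vary between trackers, so the mapping is configurable via
:class:`ColumnDialect`. Coordinates are converted to µm at ingest
(pixel value × pixel size) and all downstream math is in µm and minutes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .errors import (
    ParameterError,
    TrackFormatError,
    TrackIntegrityError,
    TrackParseError,
)
from .tracks import SegmentMetrics, SpheroidGeometry, Track, TrackSet

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ColumnDialect:
    """Names of the columns holding track id, frame index and coordinates."""

    track_id: str = "track_id"
    frame: str = "frame"
    x: str = "x"
    y: str = "y"

    @property
    def required(self) -> tuple[str, str, str, str]:
        return (self.track_id, self.frame, self.x, self.y)


DEFAULT_DIALECT = ColumnDialect()


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_tracks(
    path: PathLike,
    pixel_size: float,
    frame_interval: float,
    dialect: ColumnDialect = DEFAULT_DIALECT,
    sep: Optional[str] = None,
    provenance: str = "",
) -> TrackSet:
    """Read a delimited track table into a :class:`TrackSet`.

    Parameters
    ----------
    path:
        CSV/TSV file with one row per (cell, frame). The delimiter is
        inferred from the extension (.tsv/.txt/.tab → tab, else comma)
        unless ``sep`` is given.
    pixel_size:
        µm per pixel; coordinates in the file are multiplied by this.
    frame_interval:
        minutes per frame. Neither this nor ``pixel_size`` has a default:
        they are acquisition facts the caller must supply.
    dialect:
        Column-name mapping for track id, frame, x, y.

    Points of each track are sorted by frame, so the row order of the file
    does not affect the result.
    """
    path = Path(path)
    if pixel_size <= 0:
        raise ParameterError(f"pixel_size must be > 0, got {pixel_size}")
    if frame_interval <= 0:
        raise ParameterError(f"frame_interval must be > 0, got {frame_interval}")
    if not path.exists():
        raise FileNotFoundError(path)

    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, skipinitialspace=True)
    missing = [c for c in dialect.required if c not in df.columns]
    if missing:
        raise TrackFormatError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )

    def _numeric(col: str) -> pd.Series:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax())
            # +2: one for the header line, one for 1-based file rows
            raise TrackParseError(
                f"{path.name}: non-numeric value {raw[row]!r} in column "
                f"{col!r} at file row {row + 2}"
            )
        if out.isna().any():
            row = int(out.isna().idxmax())
            raise TrackParseError(
                f"{path.name}: empty value in column {col!r} at file row {row + 2}"
            )
        return out

    frames = _numeric(dialect.frame)
    xs = _numeric(dialect.x) * pixel_size
    ys = _numeric(dialect.y) * pixel_size
    ids = df[dialect.track_id].astype(str)

    dup = pd.DataFrame({"id": ids, "frame": frames}).duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise TrackIntegrityError(
            f"{path.name}: duplicate (cell_id, frame) pair "
            f"({ids[row]!r}, {int(frames[row])})"
        )

    tracks: list[Track] = []
    table = pd.DataFrame({"id": ids, "frame": frames, "x": xs, "y": ys})
    for cell_id, grp in table.groupby("id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                cell_id=str(cell_id),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                x=grp["x"].to_numpy(dtype=np.float64),
                y=grp["y"].to_numpy(dtype=np.float64),
            )
        )
    return TrackSet(
        tracks=tracks,
        frame_interval=float(frame_interval),
        pixel_size=float(pixel_size),
        provenance=provenance or f"read from {path.name}",
    )


def write_tracks(ts: TrackSet, path: PathLike, sep: Optional[str] = None) -> Path:
    """Write a TrackSet as a flat table (coordinates in µm).

    Reading the file back with ``pixel_size=1`` reproduces the TrackSet up
    to floating-point printing precision.
    """
    path = Path(path)
    rows = [
        {"track_id": t.cell_id, "frame": int(f), "x": x, "y": y}
        for t in ts.tracks
        for f, x, y in zip(t.frames, t.x, t.y)
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"]).to_csv(
        path, sep=_sep_for(path, sep), index=False
    )
    return path


def write_metadata(ts: TrackSet, path: PathLike) -> Path:
    """JSON sidecar with acquisition metadata and spheroid geometry."""
    path = Path(path)
    meta = {
        "frame_interval": ts.frame_interval,
        "pixel_size": ts.pixel_size,
        "provenance": ts.provenance,
        "spheroid": dataclasses.asdict(ts.spheroid) if ts.spheroid else None,
    }
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_metadata(path: PathLike) -> dict:
    meta = json.loads(Path(path).read_text())
    if meta.get("spheroid"):
        meta["spheroid"] = SpheroidGeometry(**meta["spheroid"])
    return meta


@dataclass(frozen=True)
class Violation:
    """One broken rule: which cell (or the trackset itself), which rule.

    severity "error" marks an invariant breach; "warning" marks data that
    is structurally valid but unusable for kinematics (single-point track).
    """

    cell_id: Optional[str]
    rule: str
    detail: str = ""
    severity: str = "error"


def validate_trackset(ts: TrackSet) -> list[Violation]:
    """Report every invariant violation; never raises on invalid data.

    Returns an empty list iff the TrackSet and all its tracks satisfy the
    container invariants and every track is usable for kinematics.
    """
    out: list[Violation] = []
    if not np.isfinite(ts.frame_interval) or ts.frame_interval <= 0:
        out.append(Violation(None, "frame_interval > 0", f"got {ts.frame_interval}"))
    if not np.isfinite(ts.pixel_size) or ts.pixel_size <= 0:
        out.append(Violation(None, "pixel_size > 0", f"got {ts.pixel_size}"))

    seen: dict[str, int] = {}
    for t in ts.tracks:
        seen[t.cell_id] = seen.get(t.cell_id, 0) + 1
    for cid, n in seen.items():
        if n > 1:
            out.append(Violation(cid, "cell_ids unique", f"{n} tracks share id"))

    for t in ts.tracks:
        if len(t) == 0:
            out.append(Violation(t.cell_id, "at least 1 point"))
            continue
        if np.any(t.frames < 0):
            out.append(Violation(t.cell_id, "frames non-negative"))
        if len(t) > 1 and np.any(np.diff(t.frames) <= 0):
            out.append(Violation(t.cell_id, "strictly increasing frames"))
        if not (np.all(np.isfinite(t.x)) and np.all(np.isfinite(t.y))):
            out.append(Violation(t.cell_id, "coordinates finite"))
        if len(t) == 1:
            out.append(
                Violation(
                    t.cell_id,
                    "kinematics requires >= 2 points",
                    "single-point track retained but unusable",
                    severity="warning",
                )
            )
    return out


_METRIC_COLUMNS = [
    "cell_id",
    "segment",
    "n_steps",
    "d_total",
    "disp",
    "straightness",
    "mean_velocity",
    "straightness_defined",
    "rm_label",
]


def metrics_to_frame(metrics: Iterable[SegmentMetrics]) -> pd.DataFrame:
    rows = [dataclasses.asdict(m) for m in metrics]
    return pd.DataFrame(rows, columns=_METRIC_COLUMNS)


def write_metrics_table(
    metrics: Iterable[SegmentMetrics] | pd.DataFrame, path: PathLike
) -> Path:
    """Write per-(cell, segment) metrics as CSV with a header.

    Floats are written with full repr precision, so the table round-trips
    through any generic CSV reader well below 1e-9 relative error.
    """
    path = Path(path)
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_to_frame(metrics)
    df.to_csv(path, index=False)
    return path


def read_metrics_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
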