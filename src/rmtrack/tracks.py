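"""Core containers for 2D cell-track data.

A :class:`Track` is one cell's ordered (frame, x, y) sequence in physical
units (µm); a :class:`TrackSet` bundles the tracks of a field of view with
its acquisition metadata (frame interval in minutes, pixel size used at
ingest) and, once known, the injury-spheroid geometry. All downstream
kinematics work in µm and minutes.

Coordinates are stored as numpy arrays rather than per-point objects; the
:class:`TrackPoint` named tuple is a convenience view for iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

from .errors import ParameterError

SEGMENT_LABELS = ("approach", "within", "reverse", "whole")


class TrackPoint(NamedTuple):
    """One observation of one cell: frame index, time (min), position (µm)."""

    frame: int
    time: float
    x: float
    y: float


@dataclass(frozen=True)
class SpheroidGeometry:
    """Injury-site geometry: center (µm) and the contact radius (µm).

    A cell is "in contact" with the injury site when its radial distance
    from the center is at most ``radius`` (boundary inclusive).
    """

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ParameterError(f"radius must be > 0, got {self.radius}")
        if not (np.isfinite(self.center_x) and np.isfinite(self.center_y)):
            raise ParameterError("spheroid center coordinates must be finite")


@dataclass
class Track:
    """One cell's ordered positions.

    frames must be strictly increasing non-negative integers; gaps are
    allowed (missed detections) and are handled by time-weighting in the
    velocity computation, never by interpolation.
    """

    cell_id: str
    frames: np.ndarray  # shape (n,), int
    x: np.ndarray  # shape (n,), µm
    y: np.ndarray  # shape (n,), µm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ParameterError(
                f"track {self.cell_id!r}: frames/x/y lengths differ"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def times(self, frame_interval: float) -> np.ndarray:
        """Time of each point in minutes: frame × frame_interval."""
        return self.frames * float(frame_interval)

    def points(self, frame_interval: float) -> Iterator[TrackPoint]:
        for f, x, y in zip(self.frames, self.x, self.y):
            yield TrackPoint(int(f), float(f) * frame_interval, float(x), float(y))

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Track":
        """A new track restricted to the given point indices (order kept)."""
        idx = np.asarray(indices, dtype=np.intp)
        return replace(self, frames=self.frames[idx], x=self.x[idx], y=self.y[idx])


@dataclass
class AlignedTrack(Track):
    """A track in the spheroid-centered frame (injury center at the origin).

    Produced by translating every point by minus the spheroid center, so
    all inter-point distances are identical to the source track's.
    """

    spheroid: Optional[SpheroidGeometry] = None


@dataclass
class TrackSet:
    """The tracked cells of one field of view plus acquisition metadata."""

    tracks: list[Track] = field(default_factory=list)
    frame_interval: float = 1.0  # minutes per frame
    pixel_size: float = 1.0  # µm per pixel used at ingest
    spheroid: Optional[SpheroidGeometry] = None
    provenance: str = ""

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def cell_ids(self) -> list[str]:
        return [t.cell_id for t in self.tracks]

    def get(self, cell_id: str) -> Track:
        for t in self.tracks:
            if t.cell_id == cell_id:
                return t
        raise KeyError(cell_id)


@dataclass
class SegmentMetrics:
    """Kinematic summary of one migratory segment of one cell.

    straightness is displacement / total path length, in [0, 1]; it is NaN
    (with ``straightness_defined`` False) on a zero-length path, where both
    limits 0 and 1 are defensible and the choice is left to the analyst.
    """

    cell_id: str
    segment: str  # one of SEGMENT_LABELS
    n_steps: int
    d_total: float  # µm
    disp: float  # µm
    straightness: float  # dimensionless, NaN when undefined
    mean_velocity: float  # µm/min
    straightness_defined: bool = True
    rm_label: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.segment not in SEGMENT_LABELS:
            raise ParameterError(f"unknown segment label {self.segment!r}")
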