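"""Radius-contact classification of reverse-migrated cells.

A cell contacts the injury site at slice i when its spheroid-centered
radial distance satisfies √(x_i² + y_i²) ≤ radius (boundary inclusive).
Each contacting track is partitioned into three contiguous segments:

* approach — all points strictly before the first contact,
* within   — first contact through last contact inclusive (temporary
  excursions outside the radius between the two are absorbed here, since
  the reverse segment is defined from the LAST exit with no re-entry),
* reverse  — all points strictly after the last contact.

A never-contacting track is all approach. A cell is labelled
reverse-migrated (rM) when it contacted the site, its reverse segment has
at least two points, and its final radial distance exceeds the radius by
at least ``min_reverse_displacement`` (default 0: pure contact-and-exit
definition; the minimum-travel requirement is exposed as a parameter
because it is a qualitative criterion with no canonical value).

Contact is evaluated on recorded point positions only, not on chords
between frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParameterError
from .io import metrics_to_frame
from .kinematics import align_to_spheroid, segment_kinematics
from .tracks import AlignedTrack, SegmentMetrics, SpheroidGeometry, Track, TrackSet


@dataclass
class SegmentedTrack:
    """Index partition of one track into approach / within / reverse.

    Each range is a half-open (start, stop) pair into the track's point
    indices; the three ranges are contiguous, ordered and exhaustive when
    the cell contacted the spheroid, and approach spans everything when it
    did not.
    """

    cell_id: str
    approach: tuple[int, int]
    within: tuple[int, int]
    reverse: tuple[int, int]
    contacted: bool
    rm_label: bool

    def indices(self, which: str) -> np.ndarray:
        start, stop = getattr(self, which)
        return np.arange(start, stop)

    def n_points(self, which: str) -> int:
        start, stop = getattr(self, which)
        return stop - start


def _require_aligned(track: AlignedTrack) -> None:
    if not isinstance(track, AlignedTrack):
        raise AlignmentError(
            f"track {getattr(track, 'cell_id', '?')!r} is not spheroid-aligned; "
            "call align_to_spheroid first"
        )


def radial_distances(track: AlignedTrack) -> np.ndarray:
    """Distance of each point from the spheroid center (µm)."""
    _require_aligned(track)
    return np.hypot(track.x, track.y)


def contact_frames(track: AlignedTrack, radius: float) -> np.ndarray:
    """Indices of points within the contact radius (≤, boundary counts)."""
    _require_aligned(track)
    if radius <= 0:
        raise ParameterError(f"radius must be > 0, got {radius}")
    return np.flatnonzero(radial_distances(track) <= radius)


def segment_track(
    track: AlignedTrack,
    radius: float,
    min_reverse_displacement: float = 0.0,
) -> SegmentedTrack:
    """Partition a track by the first-contact / last-exit rule and label it."""
    if min_reverse_displacement < 0:
        raise ParameterError(
            f"min_reverse_displacement must be >= 0, got {min_reverse_displacement}"
        )
    n = len(track)
    contacts = contact_frames(track, radius)
    if contacts.size == 0:
        return SegmentedTrack(
            cell_id=track.cell_id,
            approach=(0, n),
            within=(n, n),
            reverse=(n, n),
            contacted=False,
            rm_label=False,
        )
    first, last = int(contacts[0]), int(contacts[-1])
    reverse = (last + 1, n)
    n_reverse = n - (last + 1)
    rm = False
    if n_reverse >= 2:
        final_overshoot = float(np.hypot(track.x[-1], track.y[-1])) - radius
        rm = final_overshoot >= min_reverse_displacement
    return SegmentedTrack(
        cell_id=track.cell_id,
        approach=(0, first),
        within=(first, last + 1),
        reverse=reverse,
        contacted=True,
        rm_label=rm,
    )


def classify_reverse_migrated(
    ts: TrackSet,
    spheroid: Optional[SpheroidGeometry] = None,
    min_reverse_displacement: float = 0.0,
) -> dict[str, bool]:
    """rM label for every cell of the set.

    Cells with fewer than 2 points cannot exhibit migration and are
    labelled False. ``spheroid`` defaults to the TrackSet's own geometry.
    """
    spheroid = spheroid or ts.spheroid
    if spheroid is None:
        raise ParameterError("spheroid geometry is required (none set on TrackSet)")
    labels: dict[str, bool] = {}
    for t in ts.tracks:
        if len(t) < 2:
            labels[t.cell_id] = False
            continue
        seg = segment_track(
            align_to_spheroid(t, spheroid), spheroid.radius, min_reverse_displacement
        )
        labels[t.cell_id] = seg.rm_label
    return labels


def cohort_segment_metrics(
    ts: TrackSet,
    spheroid: Optional[SpheroidGeometry] = None,
    frame_interval: Optional[float] = None,
    min_reverse_displacement: float = 0.0,
    include_whole: bool = True,
    velocity_convention: str = "mean_of_steps",
) -> pd.DataFrame:
    """One metrics row per (cell, non-empty segment with ≥ 2 points).

    The rows carry the cell's rM label, so the table feeds the cohort
    comparisons directly: approach vs within vs reverse velocity, and
    rM vs non-rM straightness. Cells too short for kinematics are skipped
    (their ids appear in the frame's ``attrs["skipped"]``), never abort
    the cohort.
    """
    spheroid = spheroid or ts.spheroid
    if spheroid is None:
        raise ParameterError("spheroid geometry is required (none set on TrackSet)")
    frame_interval = frame_interval if frame_interval is not None else ts.frame_interval

    rows: list[SegmentMetrics] = []
    skipped: list[str] = []
    for t in ts.tracks:
        if len(t) < 2:
            skipped.append(t.cell_id)
            continue
        at = align_to_spheroid(t, spheroid)
        seg = segment_track(at, spheroid.radius, min_reverse_displacement)
        parts = [("approach", seg.approach), ("within", seg.within),
                 ("reverse", seg.reverse)]
        if include_whole:
            parts.append(("whole", (0, len(at))))
        for label, (start, stop) in parts:
            if stop - start < 2:
                continue
            m = segment_kinematics(
                at.subset(np.arange(start, stop)),
                frame_interval,
                cell_id=t.cell_id,
                segment=label,
                velocity_convention=velocity_convention,
            )
            m.rm_label = seg.rm_label
            rows.append(m)
    df = metrics_to_frame(rows)
    df.attrs["skipped"] = skipped
    return df
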