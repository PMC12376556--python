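"""Spheroid-centered alignment and per-segment kinematics.

Alignment is a pure translation that puts the injury spheroid at the
origin: x_new = x_cell − x_sp, y_new = y_cell − y_sp. Distances, velocities
and straightness are translation invariant, so they may be computed in
either frame; the aligned frame is used throughout for interpretability.

Per step i (> 0), the distance is the Euclidean chord between consecutive
recorded points, dist_i = √((x_{i−1}−x_i)² + (y_{i−1}−y_i)²), and the
velocity is dist_i divided by the elapsed time. When consecutive rows of a
track skip g frames (missed detections), the elapsed time for that step is
g × frame_interval — the chord is NOT subdivided and no positions are
interpolated.

A segment's straightness is its net displacement divided by its total path
length: str = disp / d_total, equal to 1 for a perfectly straight path and
0 for a closed loop. On a zero-length path the ratio is undefined and is
reported as NaN with a flag, not as an exception.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .tracks import AlignedTrack, SegmentMetrics, SpheroidGeometry, Track

VelocityConvention = str  # "mean_of_steps" | "distance_over_duration"


def align_to_spheroid(track: Track, spheroid: SpheroidGeometry) -> AlignedTrack:
    """Translate a track so the spheroid center sits at (0, 0)."""
    if len(track) == 0:
        raise InsufficientDataError(f"track {track.cell_id!r} is empty")
    return AlignedTrack(
        cell_id=track.cell_id,
        frames=track.frames.copy(),
        x=track.x - spheroid.center_x,
        y=track.y - spheroid.center_y,
        spheroid=spheroid,
    )


def step_distances(track: Union[Track, AlignedTrack]) -> np.ndarray:
    """Euclidean distance of each consecutive point pair (µm); length n−1."""
    if len(track) < 2:
        raise InsufficientDataError(
            f"track {track.cell_id!r}: step distances need >= 2 points, "
            f"got {len(track)}"
        )
    return np.hypot(np.diff(track.x), np.diff(track.y))


def step_times(track: Union[Track, AlignedTrack], frame_interval: float) -> np.ndarray:
    """Elapsed time of each step (min), honouring frame gaps."""
    if frame_interval <= 0:
        raise ParameterError(f"frame_interval must be > 0, got {frame_interval}")
    if len(track) < 2:
        raise InsufficientDataError(
            f"track {track.cell_id!r}: step times need >= 2 points"
        )
    return np.diff(track.frames) * float(frame_interval)


def step_velocities(
    track: Union[Track, AlignedTrack], frame_interval: float
) -> np.ndarray:
    """Per-step speed (µm/min): chord distance over elapsed time."""
    return step_distances(track) / step_times(track, frame_interval)


def segment_kinematics(
    track: Union[Track, AlignedTrack],
    frame_interval: float,
    cell_id: str | None = None,
    segment: str = "whole",
    velocity_convention: VelocityConvention = "mean_of_steps",
) -> SegmentMetrics:
    """Total distance, displacement, straightness and mean velocity.

    velocity_convention selects between the unweighted mean of per-step
    velocities ("mean_of_steps", the default) and total segment distance
    divided by total segment duration ("distance_over_duration"); the two
    coincide when the track has no frame gaps.
    """
    cell_id = cell_id if cell_id is not None else track.cell_id
    dists = step_distances(track)  # raises on < 2 points
    d_total = float(np.sum(dists))
    disp = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    if d_total > 0.0:
        straightness = disp / d_total
        defined = True
    else:
        straightness = float("nan")
        defined = False
    times = step_times(track, frame_interval)
    if velocity_convention == "mean_of_steps":
        mean_velocity = float(np.mean(dists / times))
    elif velocity_convention == "distance_over_duration":
        mean_velocity = d_total / float(np.sum(times))
    else:
        raise ParameterError(
            f"unknown velocity_convention {velocity_convention!r}"
        )
    return SegmentMetrics(
        cell_id=cell_id,
        segment=segment,
        n_steps=len(dists),
        d_total=d_total,
        disp=disp,
        straightness=straightness,
        mean_velocity=mean_velocity,
        straightness_defined=defined,
    )
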