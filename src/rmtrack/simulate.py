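"""Synthetic neutrophil tracks for the sterile-injury MPS geometry.

The generator emulates what the live-imaging experiments record: cells
exit an endothelial lumen on one side of the field, migrate directionally
toward a circular injury spheroid at a few µm/min, slow down and dwell at
the site, and a subpopulation subsequently reverse-migrates — either back
toward the lumen or in a random direction into the matrix. Every track
carries a ground-truth behavioural label, so the contact classifier and
segment kinematics downstream can be scored against a known answer.

Motion model (biased persistent random walk, one step per frame):

* step length = speed × frame_interval, speed drawn per step from a
  normal distribution truncated at zero (mean ``speed_mean``, sd
  ``speed_sd``), multiplied by ``within_speed_factor`` while the cell is
  inside the spheroid radius;
* step heading = persistence-weighted circular mean of the previous
  heading and the current target heading, plus Gaussian angular noise;
  the target is the spheroid center during approach, a fresh uniform
  angle during dwell/residence, and the escape direction during reverse;
* on first contact the cell dwells for a geometrically distributed number
  of frames (mean ``dwell_frames_mean``) of unbiased slow motion confined
  to the spheroid, then with probability ``p_rm`` switches to reverse
  mode, otherwise keeps moving unbiasedly inside for the rest of the
  recording. Confinement re-draws the heading of any dwell/residence step
  that would leave the radius, preserving the step length exactly.

Randomness is a pure function of the parameters: each cell consumes its
own stream derived from (seed, cell index), so changing ``n_cells`` never
reshuffles the tracks of existing cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ParameterError
from .tracks import SpheroidGeometry, Track, TrackSet

_START_JITTER_RADII = 1.0  # sd of the lumen-line y jitter, in spheroid radii
_CONFINE_MAX_TRIES = 100


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the imaging experiments: ~3 fields of view × 10 cells,
    3 h at one frame per minute, a 50 µm injury radius 250 µm from the
    lumen, approach speeds of ~4 µm/min (the 3–5 µm/min range observed in
    this MPS), markedly slower motion within the site, and a reverse-
    migrating subpopulation escaping toward the lumen.
    """

    n_cells: int = 30
    n_frames: int = 180
    frame_interval: float = 1.0  # minutes
    spheroid: SpheroidGeometry = field(
        default_factory=lambda: SpheroidGeometry(0.0, 0.0, 50.0)
    )
    lumen_offset: float = 250.0  # µm, lumen start line at center_x − lumen_offset
    speed_mean: float = 4.0  # µm/min
    speed_sd: float = 1.0  # µm/min
    persistence: float = 0.6  # weight of previous heading in [0, 1]
    heading_noise_sd: float = 0.3  # radians
    dwell_frames_mean: float = 15.0
    p_rm: float = 0.3  # probability of reverse migration after dwell
    rm_mode: str = "toward_lumen"  # or "random"
    within_speed_factor: float = 0.5  # speed multiplier inside the spheroid
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ParameterError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.n_frames < 1:
            raise ParameterError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.frame_interval <= 0:
            raise ParameterError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )
        if self.lumen_offset <= 0:
            raise ParameterError(f"lumen_offset must be > 0, got {self.lumen_offset}")
        if self.speed_mean <= 0:
            raise ParameterError(f"speed_mean must be > 0, got {self.speed_mean}")
        if self.speed_sd < 0:
            raise ParameterError(f"speed_sd must be >= 0, got {self.speed_sd}")
        if not 0.0 <= self.persistence <= 1.0:
            raise ParameterError(
                f"persistence must be in [0, 1], got {self.persistence}"
            )
        if self.heading_noise_sd < 0:
            raise ParameterError(
                f"heading_noise_sd must be >= 0, got {self.heading_noise_sd}"
            )
        if self.dwell_frames_mean < 1:
            raise ParameterError(
                f"dwell_frames_mean must be >= 1, got {self.dwell_frames_mean}"
            )
        if not 0.0 <= self.p_rm <= 1.0:
            raise ParameterError(f"p_rm must be in [0, 1], got {self.p_rm}")
        if self.rm_mode not in ("toward_lumen", "random"):
            raise ParameterError(f"rm_mode must be toward_lumen|random, got {self.rm_mode!r}")
        if not 0.0 < self.within_speed_factor <= 1.0:
            raise ParameterError(
                f"within_speed_factor must be in (0, 1], got {self.within_speed_factor}"
            )


@dataclass
class CellTruth:
    """Ground truth for one cell: did it reverse-migrate, and when."""

    rm_label: bool
    entry_frame: Optional[int]  # first frame inside the radius
    exit_frame: Optional[int]  # last frame inside the radius, if it left


@dataclass
class GroundTruth:
    """Realized behavioural labels keyed by cell id."""

    cells: dict[str, CellTruth] = field(default_factory=dict)

    def __getitem__(self, cell_id: str) -> CellTruth:
        return self.cells[cell_id]

    def rm_labels(self) -> dict[str, bool]:
        return {cid: c.rm_label for cid, c in self.cells.items()}

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            cid: {
                "rm_label": c.rm_label,
                "entry_frame": c.entry_frame,
                "exit_frame": c.exit_frame,
            }
            for cid, c in self.cells.items()
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            {
                cid: CellTruth(d["rm_label"], d["entry_frame"], d["exit_frame"])
                for cid, d in raw.items()
            }
        )


def _blend_heading(previous: float, target: float, persistence: float) -> float:
    """Circular mean of two angles with weights (persistence, 1−persistence)."""
    w = persistence
    vx = w * math.cos(previous) + (1.0 - w) * math.cos(target)
    vy = w * math.sin(previous) + (1.0 - w) * math.sin(target)
    if vx == 0.0 and vy == 0.0:  # antipodal with equal weight
        return target
    return math.atan2(vy, vx)


def _draw_speed(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero, by rejection."""
    if sd == 0.0:
        return mean
    while True:
        s = rng.normal(mean, sd)
        if s >= 0.0:
            return s


def _simulate_cell(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, CellTruth]:
    p = params
    cx, cy, radius = p.spheroid.center_x, p.spheroid.center_y, p.spheroid.radius
    n = p.n_frames
    x = np.empty(n)
    y = np.empty(n)
    x[0] = cx - p.lumen_offset
    y[0] = cy + rng.normal(0.0, _START_JITTER_RADII * radius)

    mode = "approach"
    heading = math.atan2(cy - y[0], cx - x[0])
    dwell_left = 0
    will_rm = False
    escape_heading = 0.0
    entered_reverse = False
    entry_frame: Optional[int] = None

    def inside(px: float, py: float) -> bool:
        return math.hypot(px - cx, py - cy) <= radius

    for i in range(1, n):
        px, py = x[i - 1], y[i - 1]
        if mode == "approach" and inside(px, py):
            mode = "dwell"
            entry_frame = i - 1
            dwell_left = int(rng.geometric(1.0 / p.dwell_frames_mean))
            will_rm = rng.random() < p.p_rm
        elif mode == "dwell" and dwell_left == 0:
            if will_rm:
                mode = "reverse"
                entered_reverse = True
                if p.rm_mode == "toward_lumen":
                    escape_heading = math.pi  # straight back along −x
                else:
                    escape_heading = rng.uniform(-math.pi, math.pi)
            else:
                mode = "resident"

        speed = _draw_speed(rng, p.speed_mean, p.speed_sd)
        if inside(px, py):
            speed *= p.within_speed_factor
        step = speed * p.frame_interval

        if mode == "approach":
            target = math.atan2(cy - py, cx - px)
        elif mode == "reverse":
            target = escape_heading
        else:  # dwell / resident: unbiased
            target = rng.uniform(-math.pi, math.pi)
        theta = _blend_heading(heading, target, p.persistence)
        theta += rng.normal(0.0, p.heading_noise_sd) if p.heading_noise_sd > 0 else 0.0

        nx, ny = px + step * math.cos(theta), py + step * math.sin(theta)
        if mode in ("dwell", "resident") and not inside(nx, ny):
            # confinement: re-draw the heading, keep the step length
            for _ in range(_CONFINE_MAX_TRIES):
                theta = rng.uniform(-math.pi, math.pi)
                nx, ny = px + step * math.cos(theta), py + step * math.sin(theta)
                if inside(nx, ny):
                    break
            else:
                theta = math.atan2(cy - py, cx - px)  # inward always works
                nx, ny = px + step * math.cos(theta), py + step * math.sin(theta)

        x[i], y[i] = nx, ny
        heading = theta
        if mode == "dwell":
            dwell_left -= 1

    r = np.hypot(x - cx, y - cy)
    in_mask = r <= radius
    if entry_frame is None and in_mask.any():  # contact on the last frame
        entry_frame = int(np.flatnonzero(in_mask)[0])
    exit_frame: Optional[int] = None
    if in_mask.any() and not in_mask[-1]:
        exit_frame = int(np.flatnonzero(in_mask)[-1])
    rm_label = bool(entered_reverse and not in_mask[-1])
    return x, y, CellTruth(rm_label, entry_frame, exit_frame)


def simulate_trackset(params: SimulationParams) -> tuple[TrackSet, GroundTruth]:
    """Generate a labelled synthetic cohort.

    Returns the TrackSet (spheroid geometry attached, pixel_size 1 since
    coordinates are generated directly in µm) and the per-cell ground
    truth. Identical params, seed included, give bit-identical output.
    """
    params.validate()
    width = len(str(params.n_cells - 1))
    tracks: list[Track] = []
    truth = GroundTruth()
    frames = np.arange(params.n_frames, dtype=np.int64)
    for i in range(params.n_cells):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(i,))
        )
        x, y, cell_truth = _simulate_cell(params, rng)
        cid = f"cell{i:0{width}d}"
        tracks.append(Track(cell_id=cid, frames=frames.copy(), x=x, y=y))
        truth.cells[cid] = cell_truth
    ts = TrackSet(
        tracks=tracks,
        frame_interval=params.frame_interval,
        pixel_size=1.0,
        spheroid=params.spheroid,
        provenance=f"simulated (seed={params.seed}, n_cells={params.n_cells})",
    )
    return ts, truth
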