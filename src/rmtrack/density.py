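"""Cell-location heatmaps: 2D Gaussian KDE with Scott's-rule bandwidth.

The density at a grid node g is the average of product Gaussian kernels
centred on the data points,

    f(g) = (1/n) Σ_i N(g_x − x_i; h_x) · N(g_y − y_i; h_y),

with a separate bandwidth per dimension from Scott's rule,
h_j = σ_j · n^(−1/(d+4)) with d = 2, σ_j the sample standard deviation
(n − 1 denominator). The diagonal (per-dimension) form is used rather
than the full-covariance variant: the density then integrates to one and
is equivariant under translation and axis-wise scaling of the data.
A dimension with zero spread borrows the other dimension's bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import DegenerateDataError, ParameterError

_SCOTT_EXPONENT = -1.0 / 6.0  # n^(−1/(d+4)) with d = 2


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grid: extent in µm and node counts per axis."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int = 128
    ny: int = 128

    def __post_init__(self) -> None:
        if self.nx < 32 or self.ny < 32:
            raise ParameterError(
                f"grid resolution must be >= 32 per axis, got {self.nx}x{self.ny}"
            )
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ParameterError("grid extent must be non-degenerate")


@dataclass
class DensityGrid:
    """Evaluated density field.

    ``density[i, j]`` is the estimate at (x_coords[i], y_coords[j]),
    in cells per µm² (it integrates to ~1 over a sufficiently padded grid).
    """

    x_coords: np.ndarray
    y_coords: np.ndarray
    density: np.ndarray  # shape (len(x_coords), len(y_coords))
    bandwidth_x: float
    bandwidth_y: float
    n_points: int

    def integral(self) -> float:
        """Riemann sum of density × grid-cell area."""
        dx = float(self.x_coords[1] - self.x_coords[0])
        dy = float(self.y_coords[1] - self.y_coords[0])
        return float(np.sum(self.density) * dx * dy)

    def mode_node(self) -> tuple[float, float]:
        """Grid node with the highest density."""
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.x_coords[i]), float(self.y_coords[j])


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError(f"points must have shape (n, 2), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ParameterError("points must be finite")
    return pts


def scott_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Per-dimension Scott's-rule bandwidths (h_x, h_y) in µm."""
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 2:
        raise DegenerateDataError(f"Scott's rule needs >= 2 points, got {n}")
    sx = float(np.std(pts[:, 0], ddof=1))
    sy = float(np.std(pts[:, 1], ddof=1))
    if sx == 0.0 and sy == 0.0:
        raise DegenerateDataError("all points coincide; bandwidth undefined")
    factor = float(n) ** _SCOTT_EXPONENT
    hx = sx * factor
    hy = sy * factor
    if hx == 0.0:
        hx = hy
    if hy == 0.0:
        hy = hx
    return hx, hy


def default_grid(
    points: np.ndarray,
    bandwidths: tuple[float, float],
    pad_bandwidths: float = 3.0,
    nx: int = 128,
    ny: int = 128,
) -> GridSpec:
    """Data bounding box padded by a multiple of the bandwidth per axis."""
    pts = _as_points(points)
    hx, hy = bandwidths
    return GridSpec(
        x_min=float(pts[:, 0].min() - pad_bandwidths * hx),
        x_max=float(pts[:, 0].max() + pad_bandwidths * hx),
        y_min=float(pts[:, 1].min() - pad_bandwidths * hy),
        y_max=float(pts[:, 1].max() + pad_bandwidths * hy),
        nx=nx,
        ny=ny,
    )


def kde_heatmap(
    points: np.ndarray,
    grid: Optional[GridSpec] = None,
    bandwidths: Optional[tuple[float, float]] = None,
    pad_bandwidths: float = 3.0,
    resolution: int = 128,
) -> DensityGrid:
    """Evaluate the Gaussian-kernel density of cell locations on a grid.

    ``bandwidths`` overrides Scott's rule (used e.g. to compare densities
    of point sets of different size at equal smoothing). The default grid
    is the data bounding box padded by ``pad_bandwidths`` bandwidths at
    ``resolution``² nodes.
    """
    pts = _as_points(points)
    if bandwidths is None:
        try:
            bandwidths = scott_bandwidth(pts)
        except DegenerateDataError as e:
            raise DegenerateDataError(f"cannot build heatmap: {e}") from e
    hx, hy = bandwidths
    if hx <= 0 or hy <= 0:
        raise DegenerateDataError(f"bandwidths must be > 0, got ({hx}, {hy})")
    if grid is None:
        grid = default_grid(pts, bandwidths, pad_bandwidths, resolution, resolution)

    xg = np.linspace(grid.x_min, grid.x_max, grid.nx)
    yg = np.linspace(grid.y_min, grid.y_max, grid.ny)
    n = pts.shape[0]
    # product kernel separates: density = Kx @ Ky.T / n
    zx = (xg[:, None] - pts[None, :, 0]) / hx
    zy = (yg[:, None] - pts[None, :, 1]) / hy
    kx = np.exp(-0.5 * zx**2) / (hx * np.sqrt(2.0 * np.pi))
    ky = np.exp(-0.5 * zy**2) / (hy * np.sqrt(2.0 * np.pi))
    density = kx @ ky.T / n
    return DensityGrid(
        x_coords=xg,
        y_coords=yg,
        density=density,
        bandwidth_x=hx,
        bandwidth_y=hy,
        n_points=n,
    )


def write_density_csv(dg: DensityGrid, path) -> Path:
    """Density matrix as CSV: first row/column carry the grid coordinates."""
    path = Path(path)
    header = "x\\y," + ",".join(repr(float(v)) for v in dg.y_coords)
    lines = [header]
    for i, xv in enumerate(dg.x_coords):
        row = ",".join(repr(float(v)) for v in dg.density[i])
        lines.append(f"{float(xv)!r},{row}")
    path.write_text("\n".join(lines) + "\n")
    return path
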