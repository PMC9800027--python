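"""Cuboid-grid dissection: ground-truthing point clouds against biomass.

The scaffold partitions the growth volume into 4 × 4 × 6 in cuboids —
9 × 9 × 10 = 810 cells over the 36 × 36 × 60 in interior. Physically
dissected per-cuboid biomass and per-cuboid point counts, each expressed as
a fraction of the whole root system, can then be compared cell-by-cell; the
squared Pearson correlation across all cuboids summarizes agreement.
Occupancy labels (root / non-root cuboid) feed the environmental-field
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .cloudio import ColorPointCloud
from .scaffoldseg import ScaffoldGeometry, build_scaffold_geometry

__all__ = [
    "CuboidGrid",
    "build_cuboid_grid",
    "assign_points_to_cuboids",
    "read_biomass_table",
    "relative_distribution",
    "distribution_r_squared",
    "label_root_cuboids",
]

log = logging.getLogger(__name__)


@dataclass
class CuboidGrid:
    """A 3D grid of per-cuboid values (point counts or grams).

    Cells are half-open boxes [lo, hi) of size pitch × pitch × layer spacing;
    the volume itself is half-open too, so a coordinate exactly on the global
    upper boundary falls outside the grid.
    """

    nx: int
    ny: int
    nz: int
    cell_size: tuple[float, float, float]  # in
    origin: np.ndarray  # aligned-frame corner
    values: np.ndarray  # nx×ny×nz nonnegative
    outside_count: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.nx, self.ny, self.nz):
            raise ValueError(
                f"values shape {self.values.shape} != grid ({self.nx},{self.ny},{self.nz})"
            )
        if (self.values < 0).any():
            raise ValueError("cuboid values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def layer(self, iz: int) -> np.ndarray:
        """Top-down nx×ny matrix of one z-layer."""
        return self.values[:, :, iz]

    def copy_with(self, values: np.ndarray, outside: float | None = None) -> "CuboidGrid":
        return CuboidGrid(
            self.nx, self.ny, self.nz, self.cell_size, self.origin.copy(),
            np.asarray(values, float),
            self.outside_count if outside is None else outside,
        )


def build_cuboid_grid(geometry: ScaffoldGeometry | None = None) -> CuboidGrid:
    """Empty cuboid grid matching a scaffold: one cell per 4×4×6 in subunit.

    The default scaffold gives 9 × 9 cells per layer × 10 layers = 810 cells.
    """
    geom = geometry if geometry is not None else build_scaffold_geometry()
    n_side = int(round(geom.side / geom.pitch))
    if abs(n_side * geom.pitch - geom.side) > 1e-9:
        raise ValueError("scaffold side is not an integer number of pitches")
    layer_spacing = float(np.diff(geom.layer_depths).mean()) if geom.n_layers > 1 else 6.0
    nz = geom.n_layers
    return CuboidGrid(
        nx=n_side, ny=n_side, nz=nz,
        cell_size=(geom.pitch, geom.pitch, layer_spacing),
        origin=np.array([0.0, 0.0, geom.layer_depths[0]]),
        values=np.zeros((n_side, n_side, nz)),
    )


def assign_points_to_cuboids(cloud, grid: CuboidGrid) -> CuboidGrid:
    """Bin aligned-frame points into cuboids by floor division.

    Cells are half-open over [0, side) × [0, side) × [0, depth); a coordinate
    exactly on the global upper boundary counts as outside. Points outside
    the volume go to ``outside_count`` and are logged.
    Conservation: Σ counts + outside_count = N.
    """
    if isinstance(cloud, ColorPointCloud):
        if cloud.frame_tag != "aligned":
            raise ValueError("cloud must be in the aligned scaffold frame")
        pts = cloud.coords
    else:
        pts = np.asarray(cloud, float)
    rel = pts - grid.origin
    size = np.asarray(grid.cell_size)
    dims = np.array([grid.nx, grid.ny, grid.nz])
    idx = np.floor(rel / size).astype(int)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    counts = np.zeros((grid.nx, grid.ny, grid.nz))
    np.add.at(counts, (idx[inside, 0], idx[inside, 1], idx[inside, 2]), 1.0)
    n_out = int((~inside).sum())
    if n_out:
        log.info("%d of %d points fall outside the cuboid grid", n_out, len(pts))
    return grid.copy_with(counts, outside=n_out)


def read_biomass_table(path, grid: CuboidGrid) -> CuboidGrid:
    """Load per-cuboid biomass (grams) keyed by integer cell indices ix, iy, iz."""
    df = pd.read_csv(path)
    for c in ("ix", "iy", "iz", "grams"):
        if c not in df.columns:
            raise ValueError(f"biomass table lacks column {c!r}")
    vals = np.zeros((grid.nx, grid.ny, grid.nz))
    for _, row in df.iterrows():
        i, j, k = int(row.ix), int(row.iy), int(row.iz)
        if not (0 <= i < grid.nx and 0 <= j < grid.ny and 0 <= k < grid.nz):
            raise ValueError(f"biomass cell ({i},{j},{k}) outside the {grid.nx}×{grid.ny}×{grid.nz} grid")
        vals[i, j, k] += float(row.grams)
    return grid.copy_with(vals, outside=0.0)


def relative_distribution(grid: CuboidGrid) -> np.ndarray:
    """Per-cuboid fractions of the whole root system; sums to 1."""
    total = grid.total
    if total <= 0:
        raise ValueError("cannot normalize an all-zero cuboid grid")
    return grid.values / total


def distribution_r_squared(
    frac_a: np.ndarray, frac_b: np.ndarray, drop_jointly_empty: bool = False
) -> float:
    """Squared Pearson correlation of two relative distributions, cell by cell.

    By default all cuboids enter the correlation, including jointly empty
    ones; set ``drop_jointly_empty`` to exclude cells empty in both.
    """
    a = np.asarray(frac_a, float).ravel()
    b = np.asarray(frac_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("distributions must have the same shape")
    if drop_jointly_empty:
        keep = (a > 0) | (b > 0)
        a, b = a[keep], b[keep]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance across cuboids; correlation undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def label_root_cuboids(count_grid: CuboidGrid, min_points: int = 1) -> np.ndarray:
    """Boolean occupancy: a cuboid is a root cuboid iff count ≥ min_points."""
    return count_grid.values >= min_points
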