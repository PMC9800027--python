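"""3D interpolation of buried-sensor fields and root-occupancy stratification.

Fourteen sensors at three elevations cannot anchor an interpolation out to
the walls of the growth volume, so the array is first augmented with 21
boundary support points — box corners at the three sensor elevations plus
the very top and bottom, and a center point on the top — whose values are
linear combinations of the sensor readings (inverse-distance weights within
an elevation, linear extrapolation in depth for the top/bottom points).
Matric-potential values are clipped to ≤ 0 MPa, the physical ceiling for
water potential. The 35 support points then drive Delaunay-based
piecewise-linear interpolation through the volume (the griddatan approach),
rasterized onto the cuboid grid and averaged per layer within root and
non-root cuboids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay

from .cloudio import BOX_DEPTH_IN, BOX_SIDE_IN, SensorArray

__all__ = [
    "STANDARD_SENSOR_DEPTHS_IN",
    "AugmentedSupport",
    "standard_sensor_layout",
    "augment_boundary",
    "interpolate_volume",
    "rasterize_field",
    "occupancy_stratified_layer_means",
]

#: Sensor elevations: 1.25 ft, 2.5 ft and 4.25 ft below the media surface.
STANDARD_SENSOR_DEPTHS_IN = (15.0, 30.0, 51.0)


def standard_sensor_layout(
    side: float = BOX_SIDE_IN,
    depths: tuple[float, float, float] = STANDARD_SENSOR_DEPTHS_IN,
    half_arm: float = 12.0,
) -> np.ndarray:
    """The 14 standard sampling locations (inches, aligned frame).

    A cross of 5 sensors (center + 4 arms) at each of the two upper
    elevations, and the 4 arm positions without the center at the lowest.
    """
    cx = cy = side / 2.0
    arms = [(cx - half_arm, cy), (cx + half_arm, cy), (cx, cy - half_arm), (cx, cy + half_arm)]
    locs = []
    for z in depths[:2]:
        locs.append((cx, cy, z))
        locs.extend((x, y, z) for x, y in arms)
    locs.extend((x, y, depths[2]) for x, y in arms)
    return np.asarray(locs, float)


@dataclass
class AugmentedSupport:
    """Sensor points plus boundary support points, with per-frame values."""

    points: np.ndarray  # P×3
    values: pd.DataFrame  # index timestamps, P columns
    provenance: list[str]  # per point: sensor | corner_layer | corner_top | corner_bottom | center_top
    kind: str = "matric_potential"

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_added(self) -> int:
        return sum(p != "sensor" for p in self.provenance)

    def frame_values(self, timestamp) -> np.ndarray:
        return self.values.loc[timestamp].to_numpy(dtype=float)


def _idw(target: np.ndarray, points: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Inverse-distance-weighted (power 1) combination; values may be T×S."""
    d = np.linalg.norm(points - target, axis=1)
    if (d < 1e-9).any():
        return values[..., int(np.argmin(d))]
    w = 1.0 / d
    return (values * w).sum(axis=-1) / w.sum()


def _extrapolate_z(z_target, z1, v1, z2, v2):
    """Linear extrapolation in depth through two (z, value) anchors."""
    t = (z_target - z1) / (z2 - z1)
    return v1 + t * (v2 - v1)


def augment_boundary(
    array: SensorArray,
    side: float = BOX_SIDE_IN,
    depth: float = BOX_DEPTH_IN,
) -> AugmentedSupport:
    """Add the 21 boundary support points to a 3-elevation sensor array.

    Four box corners at each of five elevations (the three sensor depths plus
    z = 0 and z = ``depth``) and one center point at the top: 21 added points,
    35 total for the standard 14-sensor layout. Corner values at a sensor
    elevation are IDW (power 1) means of that elevation's sensors; top/bottom
    corner values extrapolate linearly in z through the two nearest
    sensor-elevation corners; the top center extrapolates through the two
    upper center sensors. Every added value is an affine combination of
    sensor values, so constant fields are preserved exactly. For matric
    potential all values are clipped to ≤ 0.
    """
    z_sensors = np.unique(np.round(array.locations[:, 2], 6))
    if len(z_sensors) < 2:
        raise ValueError("boundary extrapolation needs at least 2 sensor elevations")
    corners = [(0.0, 0.0), (side, 0.0), (side, side), (0.0, side)]
    T = array.frames.to_numpy(dtype=float)  # T×S
    timestamps = list(array.frames.index)

    pts: list[tuple[float, float, float]] = [tuple(p) for p in array.locations]
    vals: list[np.ndarray] = [T[:, i] for i in range(array.n_sensors)]
    prov = ["sensor"] * array.n_sensors

    # corners at each sensor elevation
    corner_vals: dict[tuple[float, float, float], np.ndarray] = {}
    for z in z_sensors:
        m = np.abs(array.locations[:, 2] - z) < 1e-6
        layer_pts = array.locations[m]
        layer_vals = T[:, m]
        for cx, cy in corners:
            target = np.array([cx, cy, z])
            v = _idw(target, layer_pts, layer_vals)
            corner_vals[(cx, cy, float(z))] = v
            pts.append((cx, cy, float(z)))
            vals.append(v)
            prov.append("corner_layer")

    z_sorted = np.sort(z_sensors)
    z_top2, z_bot2 = z_sorted[:2], z_sorted[-2:]
    for cx, cy in corners:  # very top and very bottom corners
        v_top = _extrapolate_z(0.0, z_top2[0], corner_vals[(cx, cy, float(z_top2[0]))],
                               z_top2[1], corner_vals[(cx, cy, float(z_top2[1]))])
        pts.append((cx, cy, 0.0))
        vals.append(v_top)
        prov.append("corner_top")
        v_bot = _extrapolate_z(depth, z_bot2[0], corner_vals[(cx, cy, float(z_bot2[0]))],
                               z_bot2[1], corner_vals[(cx, cy, float(z_bot2[1]))])
        pts.append((cx, cy, depth))
        vals.append(v_bot)
        prov.append("corner_bottom")

    # top-center point through the two upper center sensors (or layer IDW
    # at the center if a layer has no exact center sensor)
    center = side / 2.0
    center_vals = []
    for z in z_sorted[:2]:
        m = np.abs(array.locations[:, 2] - z) < 1e-6
        center_vals.append(
            _idw(np.array([center, center, z]), array.locations[m], T[:, m])
        )
    v_ct = _extrapolate_z(0.0, z_sorted[0], center_vals[0], z_sorted[1], center_vals[1])
    pts.append((center, center, 0.0))
    vals.append(v_ct)
    prov.append("center_top")

    values = pd.DataFrame(
        np.column_stack(vals), index=timestamps,
        columns=[f"P{i:02d}" for i in range(len(pts))],
    )
    if array.kind == "matric_potential":
        values = values.clip(upper=0.0)
    return AugmentedSupport(
        points=np.asarray(pts, float), values=values, provenance=prov, kind=array.kind,
    )


def interpolate_volume(
    support: AugmentedSupport, queries: np.ndarray, timestamp=None
) -> np.ndarray:
    """Piecewise-linear (Delaunay barycentric) interpolation at query points.

    Exact at support points and on affine fields. Queries outside the convex
    hull of the support return NaN — flagged missing, never extrapolated.
    Returns Q values for one timestamp, or a T×Q array for all frames.
    """
    queries = np.atleast_2d(np.asarray(queries, float))
    tri = Delaunay(support.points)
    if timestamp is not None:
        interp = LinearNDInterpolator(tri, support.frame_values(timestamp))
        return interp(queries)
    out = np.empty((len(support.values), len(queries)))
    for r, ts in enumerate(support.values.index):
        out[r] = LinearNDInterpolator(tri, support.frame_values(ts))(queries)
    return out


def _cell_centers(resolution, side: float, depth: float) -> np.ndarray:
    nx, ny, nz = resolution
    xs = (np.arange(nx) + 0.5) * side / nx
    ys = (np.arange(ny) + 0.5) * side / ny
    zs = (np.arange(nz) + 0.5) * depth / nz
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def rasterize_field(
    support: AugmentedSupport,
    resolution: tuple[int, int, int] = (9, 9, 10),
    timestamp=None,
    side: float = BOX_SIDE_IN,
    depth: float = BOX_DEPTH_IN,
) -> np.ndarray:
    """Evaluate the interpolated field at grid-cell centers.

    Returns an nx×ny×nz array for one timestamp (the last frame when
    ``timestamp`` is None).
    """
    if timestamp is None:
        timestamp = support.values.index[-1]
    centers = _cell_centers(resolution, side, depth)
    vals = interpolate_volume(support, centers, timestamp=timestamp)
    return vals.reshape(resolution)


def occupancy_stratified_layer_means(
    raster: np.ndarray, occupancy: np.ndarray
) -> pd.DataFrame:
    """Per-layer field means inside root cuboids and non-root cuboids.

    Returns a DataFrame indexed by layer (0 = top) with columns mean_root,
    mean_nonroot, n_root, n_nonroot; an empty stratum yields NaN.
    """
    raster = np.asarray(raster, float)
    occupancy = np.asarray(occupancy, bool)
    if raster.shape != occupancy.shape:
        raise ValueError(
            f"raster shape {raster.shape} != occupancy shape {occupancy.shape}"
        )
    rows = []
    for iz in range(raster.shape[2]):
        layer = raster[:, :, iz]
        occ = occupancy[:, :, iz]
        valid = np.isfinite(layer)
        r = occ & valid
        n = ~occ & valid
        rows.append(
            {
                "layer": iz,
                "mean_root": layer[r].mean() if r.any() else np.nan,
                "mean_nonroot": layer[n].mean() if n.any() else np.nan,
                "n_root": int(r.sum()),
                "n_nonroot": int(n.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("layer")
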