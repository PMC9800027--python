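"""I/O for colored point clouds (PLY) and buried-sensor tables (CSV).

Coordinate convention shared by the whole package: the aligned frame has its
origin at a top-scaffold-layer corner, x and y spanning the 36 in × 36 in
interior horizontally, and z measuring depth in inches — 0 at the media
surface, increasing downward to 60 in at the bottom of the growth volume.
All geometry is handled in inches internally; report writers may also emit
centimetres (1 in = 2.54 cm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "BOX_SIDE_IN",
    "BOX_DEPTH_IN",
    "IN_PER_CM",
    "ColorPointCloud",
    "SensorArray",
    "read_ply",
    "write_ply",
    "read_sensor_table",
    "write_sensor_table",
]

#: Interior horizontal side of the growth volume, inches.
BOX_SIDE_IN = 36.0
#: Interior depth of the growth volume, inches.
BOX_DEPTH_IN = 60.0
IN_PER_CM = 1.0 / 2.54


@dataclass
class ColorPointCloud:
    """A colored 3D point cloud in inches.

    Parameters
    ----------
    coords : (N, 3) float array
        Point coordinates in inches. In the ``aligned`` frame, z is depth
        below the media surface.
    colors : (N, 3) uint8 array
        RGB colors, one per point, each channel in [0, 255].
    frame_tag : {"raw", "aligned"}
        Whether the cloud has been registered to the scaffold reference frame.
    """

    coords: np.ndarray
    colors: np.ndarray
    frame_tag: str = "raw"

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        colors = np.asarray(self.colors)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be N×3, got shape {self.coords.shape}")
        # N = 0 is allowed: segmentation stages may produce empty partitions.
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if colors.shape != self.coords.shape:
            raise ValueError(
                f"colors shape {colors.shape} does not match coords {self.coords.shape}"
            )
        if colors.min(initial=0) < 0 or colors.max(initial=0) > 255:
            raise ValueError("colors must lie within [0, 255]")
        self.colors = np.ascontiguousarray(colors, dtype=np.uint8)
        if self.frame_tag not in ("raw", "aligned"):
            raise ValueError(f"frame_tag must be 'raw' or 'aligned', got {self.frame_tag!r}")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def select(self, mask: np.ndarray, frame_tag: str | None = None) -> "ColorPointCloud":
        """Return the sub-cloud of points where ``mask`` is True (or an index array)."""
        return ColorPointCloud(
            self.coords[mask], self.colors[mask],
            frame_tag=frame_tag if frame_tag is not None else self.frame_tag,
        )

    def check_aligned_bounds(self, slack: float = 2.0) -> None:
        """Validate the aligned-frame invariant: points inside the box ± slack inches."""
        if self.frame_tag != "aligned":
            raise ValueError("bounds check only applies to aligned-frame clouds")
        lo = self.coords.min(axis=0)
        hi = self.coords.max(axis=0)
        box_hi = np.array([BOX_SIDE_IN, BOX_SIDE_IN, BOX_DEPTH_IN])
        if np.any(lo < -slack) or np.any(hi > box_hi + slack):
            raise ValueError(
                f"aligned cloud exceeds growth-volume bounds ± {slack} in: "
                f"min {lo}, max {hi}"
            )


_REQUIRED_PLY_PROPS = ("x", "y", "z", "red", "green", "blue")


def _validate_ply_header(path: Path) -> int:
    """Check the PLY header declares xyz + RGB vertex properties; return vertex count."""
    props: list[str] = []
    n_vertices = None
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path} is not a PLY file (missing 'ply' magic)")
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", errors="replace").split()
            if not tokens:
                continue
            if tokens[0] == "format" and tokens[1] not in ("ascii", "binary_little_endian"):
                raise ValueError(
                    f"unsupported PLY format {tokens[1]!r}; "
                    "expected ascii or binary_little_endian"
                )
            if tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                props.append(tokens[-1])
            elif tokens[0] == "end_header":
                break
    missing = [p for p in _REQUIRED_PLY_PROPS if p not in props]
    if missing:
        raise ValueError(
            f"PLY file {path} lacks required vertex propert"
            f"{'ies' if len(missing) > 1 else 'y'}: {', '.join(missing)}"
        )
    if not n_vertices:
        raise ValueError(f"PLY file {path} declares an empty vertex list")
    return n_vertices


def read_ply(path: str | Path, frame_tag: str = "raw") -> ColorPointCloud:
    """Read a colored point cloud from an ASCII or binary-little-endian PLY file.

    The file must declare float x, y, z and uchar red, green, blue vertex
    properties; an explicit error names any missing color property.
    """
    path = Path(path)
    n_expected = _validate_ply_header(path)
    loaded = trimesh.load(path, process=False)
    coords = np.asarray(loaded.vertices, dtype=float)
    colors = np.asarray(loaded.colors)[:, :3]  # drop alpha
    if len(coords) != n_expected:
        raise ValueError(f"{path}: read {len(coords)} vertices, header declared {n_expected}")
    return ColorPointCloud(coords, colors, frame_tag=frame_tag)


def write_ply(cloud: ColorPointCloud, path: str | Path) -> Path:
    """Write a cloud as binary-little-endian PLY (what photogrammetry tools emit)."""
    path = Path(path)
    if len(cloud) < 1:
        raise ValueError("cannot write an empty point cloud")
    rgba = np.column_stack(
        [cloud.colors, np.full(len(cloud), 255, dtype=np.uint8)]
    )
    trimesh.PointCloud(cloud.coords, colors=rgba).export(path)
    return path


@dataclass
class SensorArray:
    """Locations and time-stamped readings of a buried sensor array.

    The standard layout has 14 sampling points at three elevations. ``kind``
    names the measured quantity: matric potential (MPa, ≤ 0), temperature
    (°C) or CO₂ concentration (ppm).
    """

    sensor_ids: list[str]
    locations: np.ndarray  # S×3, inches, aligned frame
    frames: "pd.DataFrame"  # index timestamp, columns sensor_ids, values readings
    kind: str = "matric_potential"

    VALID_KINDS = ("matric_potential", "temperature", "co2")

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        if self.locations.shape != (len(self.sensor_ids), 3):
            raise ValueError("locations must be S×3 matching sensor_ids")
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"kind must be one of {self.VALID_KINDS}, got {self.kind!r}")
        if list(self.frames.columns) != list(self.sensor_ids):
            self.frames = self.frames[list(self.sensor_ids)]

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    @property
    def timestamps(self) -> list:
        return list(self.frames.index)

    def values_at(self, timestamp) -> np.ndarray:
        return self.frames.loc[timestamp].to_numpy(dtype=float)


_SENSOR_COLUMNS = ["sensor_id", "x_in", "y_in", "z_in", "timestamp", "value"]


def read_sensor_table(
    path: str | Path, kind: str = "matric_potential", expected_sensors: int = 14
) -> SensorArray:
    """Read a long-format sensor CSV (sensor_id, x_in, y_in, z_in, timestamp, value).

    Readings are grouped per timestamp. A layout with fewer than the expected
    number of sensors is accepted with a warning; duplicated
    (sensor, timestamp) rows and non-numeric values are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in _SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensor table {path} lacks columns: {', '.join(missing)}")
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"sensor table {path}: non-numeric value {df['value'].iloc[row]!r} "
            f"at data row {row + 1}"
        )
    df["value"] = pd.to_numeric(df["value"])
    dup = df.duplicated(subset=["sensor_id", "timestamp"])
    if dup.any():
        pair = df.loc[dup, ["sensor_id", "timestamp"]].iloc[0]
        raise ValueError(
            f"duplicate reading for sensor {pair['sensor_id']!r} "
            f"at timestamp {pair['timestamp']!r}"
        )
    locs = df.drop_duplicates("sensor_id").set_index("sensor_id")[["x_in", "y_in", "z_in"]]
    sensor_ids = [str(s) for s in locs.index]
    if len(sensor_ids) < expected_sensors:
        warnings.warn(
            f"sensor table has {len(sensor_ids)} sensors; "
            f"standard layout expects {expected_sensors}",
            stacklevel=2,
        )
    wide = df.pivot(index="timestamp", columns="sensor_id", values="value")
    wide.columns = [str(c) for c in wide.columns]
    return SensorArray(sensor_ids, locs.to_numpy(float), wide[sensor_ids], kind=kind)


def write_sensor_table(array: SensorArray, path: str | Path) -> Path:
    """Write a SensorArray back to the long CSV format read_sensor_table accepts."""
    rows = []
    for ts in array.timestamps:
        vals = array.values_at(ts)
        for sid, loc, v in zip(array.sensor_ids, array.locations, vals):
            rows.append(
                {"sensor_id": sid, "x_in": loc[0], "y_in": loc[1], "z_in": loc[2],
                 "timestamp": ts, "value": v}
            )
    pd.DataFrame(rows, columns=_SENSOR_COLUMNS).to_csv(path, index=False)
    return Path(path)
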