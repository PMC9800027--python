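"""Synthetic scaffold-supported root point clouds and sensor fields.

Every downstream stage of the pipeline is exercised against clouds from this
module, because each generated point carries a class label (root / scaffold /
noise) and the generator records ground truth as it builds: total centerline
length is the sum of the segments actually laid down (bookkeeping, never
re-measured), and per-cuboid point fractions are tallied at generation time.

The generator emulates the salient features of a photogrammetry
reconstruction of an excavated root system — tubular branching geometry,
brown root colors, white/green scaffold speckle along known lines, and blue
photo-studio background noise — not root growth physiology. Colors are
separable by construction: root points have CIELAB b* > 15 and blue noise
b* < 0, so segmentation precision/recall against the labels is a meaningful
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cloudio import BOX_DEPTH_IN, BOX_SIDE_IN, ColorPointCloud, SensorArray
from .scaffoldseg import ScaffoldGeometry, build_scaffold_geometry, rgb_to_cielab

__all__ = [
    "SyntheticRootParams",
    "CloudTruth",
    "LabeledCloud",
    "simulate_root_cloud",
    "make_phantom",
    "simulate_sensor_readings",
]

LABELS = ("root", "scaffold", "noise")


@dataclass
class SyntheticRootParams:
    """Knobs of the synthetic root-cloud generator. All lengths in inches."""

    n_axial: int = 15
    axial_depth_range: tuple[float, float] = (30.0, 55.0)
    axial_drift_sd: float = 0.25  # horizontal drift per 1-in growth step
    lateral_rate: float = 0.4  # branches per inch of axial root
    lateral_length_mean: float = 4.0
    tube_radius: float = 0.08
    points_per_inch: float = 25.0  # surface samples per inch of centerline
    surface_jitter_sd: float = 0.03
    root_color_mean: tuple[int, int, int] = (139, 90, 43)
    root_color_sd: float = 15.0
    scaffold_points_per_inch: float = 8.0
    scaffold_jitter_sd: float = 0.02
    noise_fraction: float = 0.02  # blue speckle count as fraction of root points
    crown_xy: tuple[float, float] = (18.0, 18.0)
    crown_radius: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_axial < 1 or self.points_per_inch <= 0 or self.tube_radius <= 0:
            raise ValueError("generator parameters must be positive")
        if not 0 < self.axial_depth_range[0] <= self.axial_depth_range[1]:
            raise ValueError("axial_depth_range must be positive and ordered")


@dataclass
class CloudTruth:
    """Ground truth recorded while the generator ran."""

    total_length: float  # in, Σ centerline segment lengths
    class_counts: dict[str, int]
    cuboid_fractions: np.ndarray | None = None  # 9×9×10 root-point fractions
    segments: np.ndarray | None = None  # K×2×3 centerline segments


@dataclass
class LabeledCloud:
    cloud: ColorPointCloud
    labels: np.ndarray  # N strings from LABELS
    truth: CloudTruth

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cloud):
            raise ValueError("labels length must equal point count")
        # volume phantoms (cube/two_cubes) have no centerline, hence no length
        if (
            self.truth.segments is not None
            and self.truth.class_counts.get("root", 0) > 0
            and self.truth.total_length <= 0
        ):
            raise ValueError("root points present but recorded total length is zero")

    def points_of(self, label: str) -> ColorPointCloud:
        return self.cloud.select(self.labels == label)


def _truth_cuboid_fractions(
    coords: np.ndarray, side: float = BOX_SIDE_IN, depth: float = BOX_DEPTH_IN,
    pitch: float = 4.0, layer: float = 6.0,
) -> np.ndarray:
    """Independent half-open binning of root points into the 9×9×10 grid."""
    nx, ny, nz = int(side / pitch), int(side / pitch), int(depth / layer)
    ix = np.floor(coords[:, 0] / pitch).astype(int)
    iy = np.floor(coords[:, 1] / pitch).astype(int)
    iz = np.floor(coords[:, 2] / layer).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    grid = np.zeros((nx, ny, nz))
    np.add.at(grid, (ix[inside], iy[inside], iz[inside]), 1.0)
    total = grid.sum()
    return grid / total if total > 0 else grid


def _sample_tube_points(
    segments: np.ndarray, radius: float, points_per_inch: float,
    jitter_sd: float, rng: np.random.Generator,
) -> np.ndarray:
    """Sample points on the surfaces of tubes around centerline segments."""
    pts = []
    for (a, b) in segments:
        a, b = np.asarray(a), np.asarray(b)
        d = b - a
        length = np.linalg.norm(d)
        if length < 1e-12:
            continue
        n = max(1, int(round(points_per_inch * length)))
        t = rng.random(n)
        axis = d / length
        # orthonormal frame around the axis
        ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        theta = rng.uniform(0, 2 * np.pi, n)
        p = (
            a + t[:, None] * d
            + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
        )
        if jitter_sd > 0:
            p = p + rng.normal(0, jitter_sd, p.shape)
        pts.append(p)
    return np.vstack(pts) if pts else np.empty((0, 3))


def _root_colors(n: int, mean: tuple[int, int, int], sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Brown-ish root colors, guaranteed CIELAB b* > 15 by construction."""
    c = np.clip(rng.normal(mean, sd, (n, 3)), 0, 255).astype(np.uint8)
    bad = rgb_to_cielab(c)[:, 2] <= 15
    c[bad] = np.asarray(mean, np.uint8)
    return c


def _blue_colors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Blue background speckle, guaranteed b* < 0 by construction."""
    c = np.clip(rng.normal((40, 70, 230), 20, (n, 3)), 0, 255).astype(np.uint8)
    bad = rgb_to_cielab(c)[:, 2] >= 0
    c[bad] = np.array([0, 0, 255], np.uint8)
    return c


def _grow_root_segments(
    p: SyntheticRootParams, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Lay down axial + lateral centerline segments; return segments and Σ length."""
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    total = 0.0
    lo, hi = p.axial_depth_range
    for _ in range(p.n_axial):
        ang = rng.uniform(0, 2 * np.pi)
        r0 = p.crown_radius * np.sqrt(rng.random())
        pos = np.array([p.crown_xy[0] + r0 * np.cos(ang),
                        p.crown_xy[1] + r0 * np.sin(ang), 0.0])
        depth_target = rng.uniform(lo, hi)
        z = 0.0
        step = 1.0
        while z < depth_target:
            dz = min(step, depth_target - z)
            drift = rng.normal(0, p.axial_drift_sd, 2) * dz
            nxt = pos + np.array([drift[0], drift[1], dz])
            nxt[0] = np.clip(nxt[0], 0.5, BOX_SIDE_IN - 0.5)
            nxt[1] = np.clip(nxt[1], 0.5, BOX_SIDE_IN - 0.5)
            seglen = float(np.linalg.norm(nxt - pos))
            segments.append((pos, nxt))
            total += seglen
            # laterals branch as a Poisson process along the axial
            for _ in range(rng.poisson(p.lateral_rate * dz)):
                length = rng.exponential(p.lateral_length_mean)
                phi = rng.uniform(0, 2 * np.pi)
                dip = rng.uniform(0.1, 0.8)  # downward component, unit vector below
                direction = np.array(
                    [np.cos(phi) * np.sqrt(1 - dip**2),
                     np.sin(phi) * np.sqrt(1 - dip**2), dip]
                )
                start = pos + rng.random() * (nxt - pos)
                end = start + length * direction
                end[0] = np.clip(end[0], 0.2, BOX_SIDE_IN - 0.2)
                end[1] = np.clip(end[1], 0.2, BOX_SIDE_IN - 0.2)
                end[2] = np.clip(end[2], 0.0, BOX_DEPTH_IN)
                llen = float(np.linalg.norm(end - start))
                if llen > 1e-9:
                    segments.append((start, end))
                    total += llen
            pos, z = nxt, nxt[2]
    return np.asarray(segments), total


def simulate_root_cloud(
    params: SyntheticRootParams | None = None,
    geometry: ScaffoldGeometry | None = None,
) -> LabeledCloud:
    """Generate a labeled synthetic mesocosm point cloud.

    Axial roots grow downward from a crown near the media surface with random
    horizontal drift; laterals branch at Poisson(lateral_rate) per inch with
    exponential lengths. Points are sampled on tube surfaces with Gaussian
    jitter and brown colors. Scaffold points are sampled along the reference
    geometry (white PVC frame, green fishing lines) and blue speckle uniformly
    in the box. Deterministic for a fixed (params, geometry): same seed,
    byte-identical output.
    """
    p = params if params is not None else SyntheticRootParams()
    geom = geometry if geometry is not None else build_scaffold_geometry()
    rng = np.random.default_rng(p.seed)

    segments, total_length = _grow_root_segments(p, rng)
    root_pts = _sample_tube_points(
        segments, p.tube_radius, p.points_per_inch, p.surface_jitter_sd, rng
    )
    if len(root_pts) == 0:
        raise ValueError("parameters produced zero root points")
    root_cols = _root_colors(len(root_pts), p.root_color_mean, p.root_color_sd, rng)

    # scaffold: vertical posts & frame edges are white PVC, interior lines green
    horizontal = np.abs(geom.segments[:, 0, 2] - geom.segments[:, 1, 2]) < 1e-9
    interior = horizontal.copy()
    for k in np.flatnonzero(horizontal):
        a, b = geom.segments[k]
        on_frame = (
            min(a[0], b[0]) <= 1e-9 and max(a[0], b[0]) >= geom.side - 1e-9
            and abs(a[1] - b[1]) < 1e-9 and (a[1] <= 1e-9 or a[1] >= geom.side - 1e-9)
        ) or (
            min(a[1], b[1]) <= 1e-9 and max(a[1], b[1]) >= geom.side - 1e-9
            and abs(a[0] - b[0]) < 1e-9 and (a[0] <= 1e-9 or a[0] >= geom.side - 1e-9)
        )
        interior[k] = not on_frame
    scaff_pts_list, scaff_cols_list = [], []
    for mask, mean_col in ((interior, (50, 180, 70)), (~interior, (250, 250, 250))):
        if mask.any():
            pts = _sample_tube_points(
                geom.segments[mask], 0.0, p.scaffold_points_per_inch,
                p.scaffold_jitter_sd, rng,
            )
            cols = np.clip(rng.normal(mean_col, 4, (len(pts), 3)), 0, 255).astype(np.uint8)
            scaff_pts_list.append(pts)
            scaff_cols_list.append(cols)
    scaff_pts = np.vstack(scaff_pts_list)
    scaff_cols = np.vstack(scaff_cols_list)

    n_noise = int(round(p.noise_fraction * len(root_pts)))
    noise_pts = rng.uniform(
        [0, 0, 0], [BOX_SIDE_IN, BOX_SIDE_IN, BOX_DEPTH_IN], (n_noise, 3)
    )
    noise_cols = _blue_colors(n_noise, rng)

    coords = np.vstack([root_pts, scaff_pts, noise_pts])
    colors = np.vstack([root_cols, scaff_cols, noise_cols])
    labels = np.array(
        ["root"] * len(root_pts) + ["scaffold"] * len(scaff_pts)
        + ["noise"] * n_noise
    )
    truth = CloudTruth(
        total_length=total_length,
        class_counts={"root": len(root_pts), "scaffold": len(scaff_pts),
                      "noise": n_noise},
        cuboid_fractions=_truth_cuboid_fractions(root_pts),
        segments=segments,
    )
    cloud = ColorPointCloud(coords, colors, frame_tag="aligned")
    return LabeledCloud(cloud, labels, truth)


def make_phantom(kind: str, seed: int = 0, **kw) -> LabeledCloud:
    """Geometric phantoms with analytically known truth.

    kind="cylinder": vertical tube, ``length`` (default 50), ``radius`` (0.5),
    ``n_points`` (5000). kind="y_branch": trunk ``trunk_length`` (30) splitting
    into two branches ``branch_length`` (10 each) at 40° from vertical.
    kind="cube": ``side`` (10), uniform interior samples. kind="two_cubes":
    two such cubes separated along x by ``gap`` (10).
    """
    rng = np.random.default_rng(seed)
    if kind == "cylinder":
        L, r = kw.get("length", 50.0), kw.get("radius", 0.5)
        n = kw.get("n_points", 5000)
        top = np.array(kw.get("top", (18.0, 18.0, 0.0)), float)
        segs = np.array([[top, top + [0, 0, L]]])
        pts = _sample_tube_points(segs, r, n / L, kw.get("jitter_sd", 0.02), rng)
        total = L
    elif kind == "y_branch":
        L1 = kw.get("trunk_length", 30.0)
        L2 = kw.get("branch_length", 10.0)
        L3 = kw.get("branch_length2", L2)
        r = kw.get("radius", 0.5)
        top = np.array(kw.get("top", (18.0, 18.0, 0.0)), float)
        split = top + [0, 0, L1]
        ang = np.deg2rad(40.0)
        d2 = np.array([np.sin(ang), 0, np.cos(ang)])
        d3 = np.array([-np.sin(ang), 0, np.cos(ang)])
        segs = np.array([[top, split], [split, split + L2 * d2], [split, split + L3 * d3]])
        n = kw.get("n_points", 5000)
        pts = _sample_tube_points(segs, r, n / (L1 + L2 + L3),
                                  kw.get("jitter_sd", 0.02), rng)
        total = L1 + L2 + L3
    elif kind in ("cube", "two_cubes"):
        side = kw.get("side", 10.0)
        n = kw.get("n_points", 10000)
        origin = np.array(kw.get("origin", (5.0, 5.0, 5.0)), float)
        pts = origin + rng.uniform(0, side, (n, 3))
        if kind == "two_cubes":
            gap = kw.get("gap", 10.0)
            pts2 = origin + [side + gap, 0, 0] + rng.uniform(0, side, (n, 3))
            pts = np.vstack([pts, pts2])
        segs, total = None, 0.0
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    cols = _root_colors(len(pts), (139, 90, 43), 10.0, rng)
    cloud = ColorPointCloud(pts, cols, frame_tag="aligned")
    truth = CloudTruth(
        total_length=total, class_counts={"root": len(pts)},
        segments=segs if kind in ("cylinder", "y_branch") else None,
    )
    return LabeledCloud(cloud, np.array(["root"] * len(pts)), truth)


def evaluate_segmentation(
    labeled: LabeledCloud, root_cloud: ColorPointCloud, label: str = "root"
) -> dict[str, float]:
    """Precision/recall of a segmented cloud against the generator's labels.

    Segmentation only ever subsets the input, so points are matched by their
    exact coordinate bytes.
    """
    keys = {c.tobytes(): lab for c, lab in zip(labeled.cloud.coords, labeled.labels)}
    out_labels = [keys[c.tobytes()] for c in root_cloud.coords]
    tp = sum(1 for l in out_labels if l == label)
    fp = len(out_labels) - tp
    total_pos = int((labeled.labels == label).sum())
    precision = tp / max(tp + fp, 1)
    recall = tp / max(total_pos, 1)
    return {"precision": precision, "recall": recall,
            "true_positive": tp, "false_positive": fp, "n_true": total_pos}


def simulate_sensor_readings(
    field_fn,
    locations: np.ndarray,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "matric_potential",
) -> SensorArray:
    """Sample a scalar field f(x, y, z, t) at sensor locations with Gaussian noise.

    The truth function is whatever the caller passed, so recovery can be
    tested against it directly.
    """
    import pandas as pd

    locations = np.asarray(locations, float)
    rng = np.random.default_rng(seed)
    ids = [f"S{i:02d}" for i in range(len(locations))]
    data = {}
    for t in times:
        vals = np.array([field_fn(x, y, z, t) for x, y, z in locations], float)
        if noise_sd > 0:
            vals = vals + rng.normal(0, noise_sd, len(vals))
        data[t] = vals
    frames = pd.DataFrame.from_dict(data, orient="index", columns=ids)
    frames.index.name = "timestamp"
    return SensorArray(ids, locations, frames, kind=kind)
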