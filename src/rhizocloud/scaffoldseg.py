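"""Scaffold alignment and root-system segmentation.

The excavated root system hangs inside a PVC-and-fishing-line scaffold:
10 square layers (36 in side) spaced 6 in apart, each strung with lines at a
4 in pitch. Segmentation proceeds in the fixed order: similarity-transform
alignment to the scaffold reference model, scaffold removal (position AND
color — roots touching the scaffold keep their points because their color is
root-like), CIELAB blue-background filtering at b* = 15, and a statistical
outlier filter standing in for manual point-cloud cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.color import rgb2lab

from .cloudio import BOX_DEPTH_IN, BOX_SIDE_IN, ColorPointCloud

__all__ = [
    "ScaffoldGeometry",
    "SimilarityTransform",
    "ColorRule",
    "default_color_rules",
    "build_scaffold_geometry",
    "estimate_similarity_transform",
    "apply_transform",
    "rgb_to_cielab",
    "remove_scaffold_points",
    "filter_blue_noise",
    "statistical_outlier_filter",
    "segment_root_cloud",
]


@dataclass
class ScaffoldGeometry:
    """Line segments and grid crossings of the scaffold reference model."""

    side: float  # in
    pitch: float  # in
    layer_depths: np.ndarray  # increasing z, in
    segments: np.ndarray  # K×2×3 line segment endpoints, in
    crossings: np.ndarray  # L×G×G×3 interior line-crossing coordinates per layer

    @property
    def n_layers(self) -> int:
        return len(self.layer_depths)

    @property
    def crossings_per_side(self) -> int:
        return self.crossings.shape[1]

    def layer_crossings(self, layer: int) -> np.ndarray:
        """Interior grid crossings of one layer as a (G²)×3 array."""
        return self.crossings[layer].reshape(-1, 3)


def build_scaffold_geometry(
    side: float = BOX_SIDE_IN,
    pitch: float = 4.0,
    layer_spacing: float = 6.0,
    n_layers: int = 10,
    top_depth: float = 0.0,
) -> ScaffoldGeometry:
    """Construct the scaffold reference model.

    Defaults give the standard build: 10 layers at z = 0, 6, …, 54 in, each a
    36 in square frame strung both ways at a 4 in pitch, yielding an 8×8
    interior grid of line crossings per layer.
    """
    if side <= 0 or pitch <= 0 or layer_spacing <= 0 or n_layers < 1:
        raise ValueError("scaffold dimensions must be positive")
    n_cells, rem = divmod(side, pitch)
    if rem > 1e-9 and pitch - rem > 1e-9:
        raise ValueError(f"pitch {pitch} in does not evenly divide side {side} in")
    n_interior = int(round(side / pitch)) - 1
    depths = top_depth + layer_spacing * np.arange(n_layers)
    offsets = pitch * (1 + np.arange(n_interior))

    segments = []
    crossings = np.empty((n_layers, n_interior, n_interior, 3))
    for li, z in enumerate(depths):
        # interior fishing lines spanning the frame in both directions
        for o in offsets:
            segments.append([[o, 0.0, z], [o, side, z]])
            segments.append([[0.0, o, z], [side, o, z]])
        # PVC frame edges
        c = [(0, 0), (side, 0), (side, side), (0, side)]
        for a, b in zip(c, c[1:] + c[:1]):
            segments.append([[a[0], a[1], z], [b[0], b[1], z]])
        gx, gy = np.meshgrid(offsets, offsets, indexing="ij")
        crossings[li] = np.stack([gx, gy, np.full_like(gx, z)], axis=-1)
    # vertical PVC corner posts tie the layers together
    for x, y in [(0, 0), (side, 0), (side, side), (0, side)]:
        segments.append([[x, y, depths[0]], [x, y, depths[-1]]])
    return ScaffoldGeometry(
        side=side, pitch=pitch, layer_depths=depths,
        segments=np.asarray(segments, float), crossings=crossings,
    )


@dataclass
class SimilarityTransform:
    """p ↦ scale · R · p + translation, with R a proper rotation (no reflection)."""

    scale: float
    rotation: np.ndarray  # 3×3
    translation: np.ndarray  # 3

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        s = 1.0 / self.scale
        return SimilarityTransform(s, Rinv, -s * Rinv @ self.translation)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
        )


def estimate_similarity_transform(
    targets: np.ndarray, controls: np.ndarray
) -> SimilarityTransform:
    """Least-squares similarity registration of picked points onto reference points.

    Solves min Σ‖s·R·targetᵢ + t − controlᵢ‖² over scale s > 0, proper rotation
    R and translation t, via the SVD of the cross-covariance with the sign of
    the smallest singular vector corrected to forbid reflections. Requires at
    least four non-coplanar target points; with fewer, or with (near-)coplanar
    targets, the rotation normal to the plane is not identifiable.
    """
    targets = np.asarray(targets, float)
    controls = np.asarray(controls, float)
    if targets.shape != controls.shape:
        raise ValueError(
            f"target/control counts differ: {targets.shape} vs {controls.shape}"
        )
    if targets.ndim != 2 or targets.shape[1] != 3 or len(targets) < 4:
        raise ValueError("need at least 4 target/control point pairs (N×3 arrays)")
    tc = targets - targets.mean(axis=0)
    cc = controls - controls.mean(axis=0)
    # coplanarity test on the centered targets
    sv = np.linalg.svd(tc, compute_uv=False)
    if sv[-1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("target points are coplanar (or collinear); pick points off-plane")
    H = tc.T @ cc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    var_t = (tc**2).sum()
    s = float((S * np.diag(D)).sum() / var_t)
    t = controls.mean(axis=0) - s * R @ targets.mean(axis=0)
    return SimilarityTransform(s, R, t)


def apply_transform(cloud: ColorPointCloud, T: SimilarityTransform) -> ColorPointCloud:
    """Transform a cloud into the scaffold reference frame. Colors are untouched."""
    return ColorPointCloud(T.apply(cloud.coords), cloud.colors, frame_tag="aligned")


def rgb_to_cielab(colors: np.ndarray) -> np.ndarray:
    """Convert N×3 RGB in [0, 255] to CIELAB via sRGB → linear RGB → XYZ(D65) → Lab."""
    colors = np.asarray(colors)
    if colors.ndim != 2 or colors.shape[1] != 3:
        raise ValueError("colors must be N×3")
    if colors.min(initial=0) < 0 or colors.max(initial=0) > 255:
        raise ValueError("RGB values must lie within [0, 255]")
    return rgb2lab(colors[np.newaxis, :, :].astype(np.uint8))[0]


@dataclass
class ColorRule:
    """A pure per-point CIELAB predicate naming a non-root scaffold color class."""

    name: str
    l_min: float = -np.inf
    l_max: float = np.inf
    a_min: float = -np.inf
    a_max: float = np.inf
    b_min: float = -np.inf
    b_max: float = np.inf

    def __call__(self, lab: np.ndarray) -> np.ndarray:
        L, a, b = lab[:, 0], lab[:, 1], lab[:, 2]
        return (
            (L > self.l_min) & (L <= self.l_max)
            & (a > self.a_min) & (a <= self.a_max)
            & (b > self.b_min) & (b <= self.b_max)
        )


def default_color_rules() -> list[ColorRule]:
    """Default thresholds for white PVC, gray shading and green fishing line.

    The classes come from the scaffold's materials; the numeric thresholds are
    engineering defaults of this package (config-exposed), not measured values.
    """
    return [
        ColorRule("white", l_min=80, a_min=-12, a_max=12, b_min=-12, b_max=12),
        ColorRule("gray", l_min=40, l_max=80, a_min=-8, a_max=8, b_min=-8, b_max=8),
        ColorRule("green", a_max=-15),
    ]


def _point_segment_distances(points: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Exact distance from each point to its nearest segment.

    Brute-force over all segments, vectorized over points, chunked over
    segments so memory stays bounded; exact point-to-segment projection.
    """
    a = segments[:, 0]
    ab = segments[:, 1] - segments[:, 0]
    ab2 = np.maximum((ab**2).sum(axis=1), 1e-300)
    best = np.full(len(points), np.inf)
    for p0 in range(0, len(points), 20000):
        pl = slice(p0, p0 + 20000)
        pts = points[pl]
        for s0 in range(0, len(segments), 64):
            sl = slice(s0, s0 + 64)
            ap = pts[:, None, :] - a[None, sl, :]  # n×k×3
            t = np.clip((ap * ab[None, sl, :]).sum(axis=2) / ab2[None, sl], 0.0, 1.0)
            closest = a[None, sl, :] + t[:, :, None] * ab[None, sl, :]
            d = np.linalg.norm(pts[:, None, :] - closest, axis=2).min(axis=1)
            np.minimum(best[pl], d, out=best[pl])
    return best


def remove_scaffold_points(
    cloud: ColorPointCloud,
    geom: ScaffoldGeometry,
    tube_radius: float = 0.4,
    rules: list[ColorRule] | None = None,
) -> tuple[ColorPointCloud, ColorPointCloud]:
    """Strip scaffold points from an aligned cloud; returns (root, removed).

    A point is removed only when BOTH tests fire: it lies within
    ``tube_radius`` of some scaffold segment AND a non-root color rule matches.
    Root points growing along the scaffold are brown and survive the color
    test, so they are retained. The two outputs partition the input.
    """
    if tube_radius <= 0:
        raise ValueError("tube_radius must be positive")
    if cloud.frame_tag != "aligned":
        raise ValueError("cloud must be aligned to the scaffold frame first")
    if rules is None:
        rules = default_color_rules()
    lab = rgb_to_cielab(cloud.colors)
    color_hit = np.zeros(len(cloud), dtype=bool)
    for rule in rules:
        color_hit |= rule(lab)
    near = np.zeros(len(cloud), dtype=bool)
    # position test only needed where color already fired
    idx = np.flatnonzero(color_hit)
    if len(idx):
        d = _point_segment_distances(cloud.coords[idx], geom.segments)
        near[idx] = d <= tube_radius
    removed = color_hit & near
    return cloud.select(~removed), cloud.select(removed)


def filter_blue_noise(cloud: ColorPointCloud, b_min: float = 15.0) -> ColorPointCloud:
    """Drop photo-studio blue background speckle: keep points with CIELAB b* ≥ b_min.

    b* = 15 separates blue reconstruction noise from brown root tissue
    (pure blue has b* ≈ −108; root browns sit well above +15). Idempotent.
    """
    lab = rgb_to_cielab(cloud.colors)
    keep = lab[:, 2] >= b_min
    if not keep.any():
        raise ValueError("blue filter would remove every point; check colors/threshold")
    return cloud.select(keep)


def statistical_outlier_filter(
    cloud: ColorPointCloud, k: int = 16, n_sigma: float = 2.0
) -> ColorPointCloud:
    """Remove sparse outliers: points whose mean k-NN distance exceeds μ + n_sigma·σ.

    Programmatic replacement for interactive post-process cleanup of residual
    speckle and scaffold remnants.
    """
    if len(cloud) <= k:
        raise ValueError(f"need more than k={k} points, got {len(cloud)}")
    tree = cKDTree(cloud.coords)
    dists, _ = tree.query(cloud.coords, k=k + 1)  # first neighbor is the point itself
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + n_sigma * mean_d.std()
    return cloud.select(mean_d <= thresh)


def segment_root_cloud(
    cloud: ColorPointCloud,
    geom: ScaffoldGeometry,
    transform: SimilarityTransform | None = None,
    tube_radius: float = 0.4,
    rules: list[ColorRule] | None = None,
    b_min: float = 15.0,
    outlier_k: int = 16,
    outlier_n_sigma: float = 2.0,
) -> tuple[ColorPointCloud, dict]:
    """Full segmentation: align → scaffold removal → blue filter → outlier filter.

    Returns the cleaned root cloud and a stage-by-stage point-count log.
    """
    log: dict = {"input": len(cloud)}
    if transform is not None:
        cloud = apply_transform(cloud, transform)
    elif cloud.frame_tag != "aligned":
        raise ValueError("provide a transform or an already-aligned cloud")
    root, removed = remove_scaffold_points(cloud, geom, tube_radius, rules)
    log["scaffold_removed"] = len(removed)
    root = filter_blue_noise(root, b_min)
    log["blue_removed"] = log["input"] - log["scaffold_removed"] - len(root)
    if len(root) > outlier_k:
        root = statistical_outlier_filter(root, outlier_k, outlier_n_sigma)
    log["outliers_removed"] = (
        log["input"] - log["scaffold_removed"] - log["blue_removed"] - len(root)
    )
    log["output"] = len(root)
    return root, log
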