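"""Global point-cloud architecture traits and depth-resolved distributions.

Traits measured directly on the cleaned root cloud: point count (a biomass
proxy), convex hull volume, PCA shape ratios (elongation λ₂/λ₁, flatness
λ₃/λ₂), maximum rooting depth, alpha-shape volumes at probe radii 0.5/1/2 in,
and solidity — the alpha(2) volume over the hull volume, quantifying how
thoroughly the root system fills the zone it explores. Vertical distributions
of biomass, hull area and solidity are discretized into 10 depth bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.stats import gaussian_kde

from .cloudio import ColorPointCloud

__all__ = [
    "AlphaShapeResult",
    "DepthProfile",
    "TraitReport",
    "convex_hull_volume",
    "pca_shape_ratios",
    "max_depth",
    "alpha_shape_volume",
    "global_solidity",
    "depth_profiles",
    "root_shoot_ratio",
    "compute_trait_report",
]

DEFAULT_ALPHAS = (0.5, 1.0, 2.0)


def _coords(cloud) -> np.ndarray:
    if isinstance(cloud, ColorPointCloud):
        return cloud.coords
    return np.asarray(cloud, float)


def convex_hull_volume(cloud) -> float:
    """Volume (in³) of the smallest convex set containing the points."""
    pts = _coords(cloud)
    if len(pts) < 4:
        raise ValueError("convex hull volume needs at least 4 points")
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as e:
        raise ValueError(f"degenerate point set (coplanar or collinear): {e}") from e


def pca_shape_ratios(cloud) -> tuple[float, float]:
    """(elongation, flatness) = (λ₂/λ₁, λ₃/λ₂) of the coordinate covariance.

    Collinear clouds have elongation 0 and an undefined flatness, returned as
    NaN with a warning; coincident points (zero PC1 variance) are an error.
    """
    pts = _coords(cloud)
    if len(pts) < 3:
        raise ValueError("PCA shape ratios need at least 3 points")
    cov = np.cov(pts.T)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.maximum(lam, 0.0)
    if lam[0] <= 0:
        raise ValueError("all points coincide; PC1 variance is zero")
    # relative floor: eigenvalues below numeric noise count as zero variance
    lam[lam < 1e-12 * lam[0]] = 0.0
    elongation = float(lam[1] / lam[0])
    if lam[1] <= 0:
        warnings.warn("points are collinear; flatness is undefined", stacklevel=2)
        return elongation, float("nan")
    return elongation, float(lam[2] / lam[1])


def max_depth(cloud) -> float:
    """Depth (in) of the deepest root point: max z in the aligned frame."""
    return float(_coords(cloud)[:, 2].max())


def _tetra_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radius of each Delaunay tetrahedron, vectorized.

    The circumcenter c satisfies 2(vᵢ − v₀)·c = ‖vᵢ‖² − ‖v₀‖² for i = 1..3;
    solved per-tetra via the 3×3 inverse. Degenerate (near-flat) tetrahedra
    get an infinite radius, which simply excludes them at any finite alpha.
    """
    v = pts[simplices]  # T×4×3
    a = v[:, 1:] - v[:, :1]  # T×3×3 rows vᵢ−v₀
    b = 0.5 * ((v[:, 1:] ** 2).sum(axis=2) - (v[:, :1] ** 2).sum(axis=2))  # T×3
    det = np.linalg.det(a)
    ok = np.abs(det) > 1e-12
    centers = np.full((len(simplices), 3), np.nan)
    if ok.any():
        centers[ok] = np.linalg.solve(a[ok], b[ok][:, :, None])[:, :, 0]
    r = np.linalg.norm(centers - v[:, 0], axis=1)
    r[~ok] = np.inf
    return r


def _tetra_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    v = pts[simplices]
    return np.abs(np.linalg.det(v[:, 1:] - v[:, :1])) / 6.0


@dataclass
class AlphaShapeResult:
    alpha: float
    volume: float  # in³
    kept_simplices: int


def alpha_shape_volume(cloud, alpha: float) -> AlphaShapeResult:
    """Volume of the alpha shape: keep Delaunay tetrahedra whose circumsphere
    radius is at most the probe radius ``alpha`` (inches), sum their volumes.

    alpha = numpy.inf keeps every tetrahedron and recovers the convex hull
    exactly; alpha below the point spacing gives 0. (Near-degenerate sliver
    tetrahedra can have circumradii far beyond the cloud's extent, so a merely
    "large" finite alpha approaches the hull volume from below.)
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    pts = _coords(cloud)
    if len(pts) < 4:
        raise ValueError("alpha shape needs at least 4 points")
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError(f"degenerate tetrahedralization: {e}") from e
    radii = _tetra_circumradii(pts, tri.simplices)
    keep = radii <= alpha
    vol = float(_tetra_volumes(pts, tri.simplices[keep]).sum()) if keep.any() else 0.0
    return AlphaShapeResult(alpha=alpha, volume=vol, kept_simplices=int(keep.sum()))


def global_solidity(cloud, alpha: float = 2.0) -> float:
    """Alpha-shape volume at alpha=2 divided by convex hull volume, in [0, 1]."""
    hull = convex_hull_volume(cloud)
    if hull <= 0:
        raise ValueError("convex hull volume is zero; solidity undefined")
    return alpha_shape_volume(cloud, alpha).volume / hull


def _polygon_area_2d(pts2: np.ndarray) -> float:
    try:
        return float(ConvexHull(pts2).volume)  # 2D "volume" is area
    except QhullError:
        return np.nan


def _alpha_area_2d(pts2: np.ndarray, alpha: float) -> float:
    """2D alpha-shape area: keep Delaunay triangles with circumradius ≤ alpha."""
    if len(pts2) < 3:
        return np.nan
    try:
        tri = Delaunay(pts2)
    except QhullError:
        return np.nan
    v = pts2[tri.simplices]  # T×3×2
    a = v[:, 1] - v[:, 0]
    b = v[:, 2] - v[:, 0]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    area2 = np.abs(cross)
    la = np.linalg.norm(v[:, 1] - v[:, 2], axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(a, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)  # circumradius = abc / (4·area)
    r[area2 < 1e-12] = np.inf
    keep = r <= alpha
    return float((area2[keep] / 2.0).sum())


@dataclass
class DepthProfile:
    """10-bin vertical distributions of biomass, hull area and solidity."""

    bin_edges: np.ndarray  # n_bins+1 depths, in
    biomass_density: np.ndarray  # per-bin point-mass fraction, sums to 1
    hull_area: np.ndarray  # per-bin mean horizontal hull area, in²
    solidity: np.ndarray  # per-bin ratio in (0, 1]
    imputed_bins: np.ndarray  # bool flags: solidity/hull spline-imputed

    @property
    def n_bins(self) -> int:
        return len(self.biomass_density)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def depth_profiles(
    cloud,
    n_bins: int = 10,
    n_slabs: int = 50,
    alpha: float = 2.0,
    depth_range: tuple[float, float] | None = None,
) -> DepthProfile:
    """Depth-resolved biomass / hull-area / solidity distributions.

    Biomass: 1D Gaussian KDE over z (Silverman bandwidth) integrated per bin
    and normalized to sum exactly 1. Hull area and solidity: the depth range
    is cut into ``n_slabs`` slabs; per slab, the 2D convex hull area and the
    2D alpha-shape area (probe radius ``alpha``) of the xy coordinates are
    computed; areas are Gaussian-smoothed across slabs and averaged per bin;
    solidity (alpha area / hull area) is cubic-spline interpolated across
    defined slabs and sampled at bin centers. Slabs with fewer than 3 points
    are undefined; bins relying on imputation are flagged, never silently
    zeroed. Bins span [0, max_depth] by default; pass ``depth_range`` for
    fixed-range binning (e.g. the full 60 in profile).
    """
    pts = _coords(cloud)
    z = pts[:, 2]
    zmax = float(z.max())
    if depth_range is None:
        lo, hi = 0.0, zmax
    else:
        lo, hi = depth_range
    if hi <= lo:
        raise ValueError("depth range must have positive extent")
    edges = np.linspace(lo, hi, n_bins + 1)

    # biomass: KDE integrated per bin, then normalized to sum exactly 1
    if np.ptp(z) < 1e-12:
        biomass = np.zeros(n_bins)
        biomass[np.clip(np.searchsorted(edges, z[0], side="right") - 1, 0, n_bins - 1)] = 1.0
    else:
        kde = gaussian_kde(z, bw_method="silverman")
        biomass = np.array(
            [kde.integrate_box_1d(edges[i], edges[i + 1]) for i in range(n_bins)]
        )
        biomass = biomass / biomass.sum()

    slab_edges = np.linspace(lo, hi, n_slabs + 1)
    slab_centers = 0.5 * (slab_edges[:-1] + slab_edges[1:])
    hull_a = np.full(n_slabs, np.nan)
    alpha_a = np.full(n_slabs, np.nan)
    for i in range(n_slabs):
        m = (z >= slab_edges[i]) & (
            z < slab_edges[i + 1] if i < n_slabs - 1 else z <= slab_edges[i + 1]
        )
        if m.sum() >= 3:
            xy = pts[m, :2]
            hull_a[i] = _polygon_area_2d(xy)
            alpha_a[i] = _alpha_area_2d(xy, alpha)

    defined = np.isfinite(hull_a) & np.isfinite(alpha_a) & (hull_a > 0)
    if defined.sum() < 2:
        raise ValueError("too few populated depth slabs to form depth profiles")

    # smooth slab hull areas (Gaussian over depth, Silverman-scaled bandwidth)
    slab_w = (hi - lo) / n_slabs
    bw = 1.06 * z.std() * len(z) ** (-1 / 5)
    sigma_slabs = max(bw / slab_w, 0.5)
    hull_s = np.interp(slab_centers, slab_centers[defined], hull_a[defined])
    hull_s = ndimage.gaussian_filter1d(hull_s, sigma_slabs, mode="nearest")
    bin_idx = np.clip(
        np.searchsorted(edges, slab_centers, side="right") - 1, 0, n_bins - 1
    )
    hull_bins = np.array([hull_s[bin_idx == b].mean() for b in range(n_bins)])

    sol_slab = alpha_a[defined] / hull_a[defined]
    spline = CubicSpline(slab_centers[defined], sol_slab)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sol_bins = np.clip(spline(centers), 1e-12, 1.0)
    imputed = np.zeros(n_bins, bool)
    for b in range(n_bins):
        in_bin = bin_idx == b
        imputed[b] = not defined[in_bin].all()

    return DepthProfile(
        bin_edges=edges, biomass_density=biomass, hull_area=hull_bins,
        solidity=sol_bins, imputed_bins=imputed,
    )


def root_shoot_ratio(root_dry_weight: float, shoot_dry_weight: float) -> float:
    """Root dry weight over shoot dry weight, rounded to 2 decimals."""
    if shoot_dry_weight <= 0:
        raise ValueError("shoot dry weight must be positive")
    if root_dry_weight <= 0:
        raise ValueError("root dry weight must be positive")
    return round(root_dry_weight / shoot_dry_weight, 2)


@dataclass
class TraitReport:
    """All global traits of one root-system point cloud."""

    point_count: int
    convex_hull_volume_in3: float
    elongation: float
    flatness: float
    max_depth_in: float
    alpha_volumes_in3: dict[float, float]
    solidity: float
    depth_profile: DepthProfile | None = None
    total_root_length_in: float | None = None
    root_shoot_ratio: float | None = None

    def to_dict(self) -> dict:
        d = {
            "point_count": self.point_count,
            "convex_hull_volume_in3": self.convex_hull_volume_in3,
            "convex_hull_volume_cm3": self.convex_hull_volume_in3 * 2.54**3,
            "elongation": self.elongation,
            "flatness": self.flatness,
            "max_depth_in": self.max_depth_in,
            "max_depth_cm": self.max_depth_in * 2.54,
            "alpha_volumes_in3": {str(k): v for k, v in self.alpha_volumes_in3.items()},
            "solidity": self.solidity,
        }
        if self.total_root_length_in is not None:
            d["total_root_length_in"] = self.total_root_length_in
            d["total_root_length_cm"] = self.total_root_length_in * 2.54
        if self.root_shoot_ratio is not None:
            d["root_shoot_ratio"] = self.root_shoot_ratio
        if self.depth_profile is not None:
            p = self.depth_profile
            d["depth_profile"] = {
                "bin_edges_in": p.bin_edges.tolist(),
                "biomass_density": p.biomass_density.tolist(),
                "hull_area_in2": p.hull_area.tolist(),
                "solidity": p.solidity.tolist(),
                "imputed_bins": p.imputed_bins.tolist(),
            }
        return d


def compute_trait_report(
    cloud,
    alphas=DEFAULT_ALPHAS,
    n_bins: int = 10,
    total_root_length_in: float | None = None,
    root_dry_weight: float | None = None,
    shoot_dry_weight: float | None = None,
    with_depth_profile: bool = True,
) -> TraitReport:
    """Compute every global trait on a cleaned, aligned root cloud."""
    pts = _coords(cloud)
    hull = convex_hull_volume(pts)
    elo, fla = pca_shape_ratios(pts)
    alpha_vols = {a: alpha_shape_volume(pts, a).volume for a in alphas}
    sol = alpha_vols.get(2.0, alpha_shape_volume(pts, 2.0).volume) / hull
    ratio = None
    if root_dry_weight is not None and shoot_dry_weight is not None:
        ratio = root_shoot_ratio(root_dry_weight, shoot_dry_weight)
    return TraitReport(
        point_count=len(pts),
        convex_hull_volume_in3=hull,
        elongation=elo,
        flatness=fla,
        max_depth_in=max_depth(pts),
        alpha_volumes_in3=alpha_vols,
        solidity=sol,
        depth_profile=depth_profiles(pts, n_bins=n_bins) if with_depth_profile else None,
        total_root_length_in=total_root_length_in,
        root_shoot_ratio=ratio,
    )
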