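# Methods

This document records the models, algorithms, parameter defaults and known
limitations behind `rhizocloud`. Everything here is a design decision of
this package; defaults are exposed through dataclasses and function
arguments so none of them is load-bearing for correctness.

## Coordinate model

The growth volume is a 36 in × 36 in × 60 in box containing a regular
scaffold: a square line grid of 4-inch pitch at ten depth layers spaced
6 in apart (z = 0, 6, …, 54), held by four corner posts. The **aligned
frame** places the origin at a top scaffold corner, x and y across the
interior, and z as depth, increasing downward. All internal geometry is in
inches; report writers also emit centimetres (1 in = 2.54 cm). Clouds carry
a `frame_tag` (`raw` or `aligned`) so pipeline stages can enforce their
preconditions.

## Registration (`scaffoldseg`)

Raw photogrammetry clouds are registered to the scaffold frame by a
similarity transform (uniform scale + rotation + translation, reflections
excluded) estimated from matched control points on the scaffold:

- Closed-form Procrustes solution via SVD of the centered cross-covariance;
  the rotation's determinant is forced to +1 by sign-correcting the
  smallest singular direction.
- Scale is the standard least-squares estimate
  s = Σᵢ σᵢ dᵢ / Var(targets) from the singular values.
- Coplanar or degenerate control sets (smallest singular value below
  1e-8 of the largest) are rejected — with fewer than 3 well-spread
  correspondences the transform is not identifiable.

Recovery on exact correspondences is at numerical precision (≪ 1e-9 in);
with isotropic jitter of standard deviation σ the residual RMS stays below
about 3σ (property-tested).

## Segmentation (`scaffoldseg`)

Colors are converted from sRGB to CIELAB (D65, via scikit-image). Anchors:
white → L* = 100, a* ≈ b* ≈ 0; pure blue (0, 0, 255) → b* ≈ −107.86; a
typical root brown (139, 90, 43) → b* ≈ +34.7. Stages run in a fixed order,
each returning a partition so that input = kept + removed:

1. **Scaffold removal.** A point is scaffold iff it lies within
   `tube_radius` (default 0.4 in) of a scaffold segment **and** a scaffold
   color rule fires (white: L* > 80, |a*| < 12, |b*| < 12; gray:
   40 < L* ≤ 80, |a*| < 8, |b*| < 8; green: a* < −15). The conjunction
   protects root points that merely pass near a line.
   Point-to-segment distances are computed exactly and chunked
   (20 000 points × 64 segments) to bound memory.
2. **Blue-noise filter.** Points with b* < 15 are removed: blue dye
   particles suspended in the medium reconstruct as deeply negative-b*
   speckle, while root tissue is firmly on the yellow side of b* = 15.
   The filter is idempotent, and erroring when it would remove everything
   guards against misconfigured inputs.
3. **Statistical outlier removal.** Points whose mean distance to their
   k = 16 nearest neighbors exceeds the cloud mean by more than
   n_sigma = 2 standard deviations are dropped (the standard
   statistical-outlier-removal filter).

On the labeled synthetic mesocosm cloud (102 k points) segmentation scores
precision 1.00 / recall 0.97 and runs in ~2 s.

## Traits (`traits`)

- **Convex hull volume** via Qhull; degenerate (coplanar) inputs raise.
- **PCA shape ratios**: elongation λ₂/λ₁ and flatness λ₃/λ₂ of the
  covariance eigenvalues. Eigenvalues below 1e-12 of the largest are
  floored to exact zero; collinear clouds return elongation 0 with
  flatness NaN and a warning (the flatness denominator is zero).
- **Alpha-shape volume**: Delaunay tetrahedralization, keep tetrahedra with
  circumradius ≤ α, sum their volumes. Circumradii are computed by a
  batched linear solve. `alpha = np.inf` keeps every tetrahedron and is
  **exactly** the convex hull volume — the correct large-α limit. Note
  that no finite α reaches the hull: boundary sliver tetrahedra have
  circumradii far beyond the cloud's diameter, so finite-α volumes
  approach the hull from below (α = box diagonal typically lands within
  ~1–3 % of the hull). The implementation matches an independent
  per-simplex brute-force oracle to 1e-8 on 400–500-point clouds.
- **Solidity** = alpha-shape volume at α = 2 in divided by hull volume —
  how thoroughly the root fills its explored envelope.
- **Depth profiles** over ten 6-inch bins: (a) a biomass-proxy density from
  a 1D Gaussian KDE of point depths (Silverman bandwidth) integrated per
  bin and normalized to sum to 1; (b) per-depth 2D convex-hull and
  alpha-shape areas from 50 horizontal slabs, lightly smoothed
  (Gaussian, σ = 1 slab) and resampled at bin centers by cubic spline;
  slabs with too few points are imputed and flagged. 2D alpha shapes use
  triangle circumradius abc / (2·|cross|).
- **Root:shoot ratio** = root dry weight / shoot dry weight, reported to
  2 decimals as is conventional for such tables.

## Skeletonization (`rootskel`)

Total root length needs a 1D curve skeleton. The package uses Laplacian
contraction:

1. Build the symmetric k-NN graph (k = 12) and its inverse-distance-weighted
   graph Laplacian L = D − W (edge weights clamped below at 1e-4 of the
   mean edge length).
2. Iteratively solve the regularized least-squares system
   [w_L·L; W_H] P′ = [0; W_H·P] via the sparse normal equations
   (w_L² LᵀL + diag(w_H²)) P′ = diag(w_H²) P, one axis at a time.
   w_L starts at 1 / (10 · mean k-NN distance) and is amplified ×3 per
   iteration; the per-point attraction w_H grows as the local neighborhood
   extent collapses (original / current mean incident-edge length).
   Iteration stops on a plateau (total extent no longer decreasing) or
   when extent falls below 1 % of its initial value; ≤ 10 iterations.
   Connected components are contracted independently. Because each update
   is an affine combination of the inputs with rows summing to one,
   collinear input remains exactly on its line.
3. **Graph assembly**: farthest-point sampling of the contracted points at
   radius h (deterministically seeded from the lowest index); every point
   joins its nearest sample's source set; two nodes connect iff their
   source sets contain k-NN neighbors; node positions are the centroids of
   their **original** source points. Each component is then reduced to its
   Euclidean minimum spanning tree: neighbor-set adjacency also links
   nodes two steps apart along a branch, and such a shortcut closes a
   triangle in which it is the longest edge, so the MST cycle property
   removes exactly the shortcuts (root systems are trees; genuine loops
   are not expected).
4. **Length**: sum of edge lengths after pruning terminal chains shorter
   than the prune length (leaf-to-leaf chains are never pruned), plus a
   tip extension per remaining leaf — the farthest projection of the
   leaf's original source points along its incident edge direction, which
   compensates the half-cell truncation of centroids at root tips.

Defaults h = 4 × mean k-NN distance and prune = 2h were chosen on geometric
phantoms *before* freezing the acceptance thresholds: over 20 random tubes
the length error was at most 4.5 % (mean 2.3 %), and the 50-inch cylinder
and Y-branch phantoms recover within 5 %.

**Known limitation.** On dense full-system synthetic clouds (40 k root
points, 15 axial roots with many contacting laterals) total length
under-recovers by roughly 35 %: branches that touch or interleave merge
during contraction, which is the documented failure mode of contraction
skeletons on dense root crowns. Phantom-scale accuracy is the supported
accuracy claim; full-cloud lengths should be treated as lower bounds.

## Cuboid grid (`cuboid`)

The scaffold dissects the volume into 4 × 4 × 6 in cuboids: 9 × 9 per
layer × 10 layers = 810 cells. Cells are **strictly half-open** over
[0, 36) × [0, 36) × [0, 60): a coordinate exactly on the global upper
boundary (e.g. x = 36) is outside the grid and counts toward
`outside_count`; conservation Σ counts + outside = N always holds. Point
distributions and dissected biomass are each normalized to fractions of
their totals and compared cell-by-cell with the squared Pearson correlation
over all 810 cells (an option drops jointly-empty cells). Occupancy labels
(count ≥ 1 by default) mark root versus non-root cuboids.

## Sensor fields (`envflux`)

The standard array has 14 sampling points: a cross of five (center + four
arms at 12 in) at 15 in and 30 in depth, and the four arm positions at
51 in. Fourteen interior points cannot anchor interpolation to the walls,
so the support is augmented with 21 boundary points (35 total):

- the four box corners at each of the three sensor elevations
  (inverse-distance-weighted, power 1, within the elevation),
- the four corners at z = 0 and z = 60 (linear extrapolation in depth
  through the two nearest corner anchors),
- one top-center point (linear extrapolation through the two upper center
  values).

Every added value is an affine combination of sensor readings, so constant
fields are preserved exactly and a purely depth-dependent affine field is
extrapolated exactly. Matric-potential values are clipped to ≤ 0 MPa (the
physical ceiling); because clipping and augmentation are both monotone and
the augmentation is affine, clipping before or after augmentation agrees on
physically valid data.

Interpolation is piecewise-linear over the Delaunay tetrahedralization of
the 35 support points (barycentric weights): exact at support points,
exact on affine fields, and NaN outside the support hull — flagged missing,
never extrapolated. Fields are rasterized at cuboid-cell centers
(9 × 9 × 10 by default) and summarized as per-layer means inside root
versus non-root cuboids; empty strata yield NaN, and NaN raster cells are
excluded from means.

## Synthetic data (`synthroot`)

The generator produces labeled clouds with recorded ground truth so every
pipeline stage can be scored without physical data:

- **Root systems**: 15 axial roots from a crown at (18, 18), grown in
  1-inch steps with Gaussian lateral drift (σ = 0.25 in/step) to depths of
  30–55 in; Poisson lateral branching (0.4/in) with exponential lateral
  lengths (mean 4 in); points sampled on 0.08-in tubes at 25 points/in;
  brown colors (mean RGB (139, 90, 43), σ = 15, resampled to guarantee
  b* > 15). Truth records total centerline length, class counts, per-label
  points, and independently binned cuboid fractions.
- **Scaffold**: green interior lines and white frame points at 8 points/in.
- **Noise**: 2 % blue speckle (b* < 0 guaranteed).
- **Phantoms**: cylinder, 40° Y-branch, cube, two separated cubes — with
  closed-form truth for length/volume tests.
- **Sensor readings**: any caller-supplied field f(x, y, z, t) sampled at
  given locations with optional Gaussian noise.

Scope: the generator is for validation, not biological realism — no root
diameter taper, no gravitropism curvature model, no soil heterogeneity.
Generator parameters were never adjusted in response to test outcomes; all
tolerance choices were fixed from phantom measurements first.

## Problem sizes and runtime

Typical sizes used in tests and examples: synthetic mesocosm cloud ~102 k
points (segmentation ~2 s); skeletonization 5–6 k-point phantoms ~3 s each,
42 k-point full cloud ~33 s; alpha-shape oracle comparisons at 400–500
points; interpolation/raster work is sub-second. The full test suite runs
in a few minutes on one CPU; `scripts/acceptance.py` in well under a
minute.
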