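# rhizocloud

3D point-cloud phenotyping of root systems grown in large instrumented
mesocosms.

## The problem

Field-scale root system architecture (RSA) is hard to measure: pots are too
small, field excavation destroys spatial structure. One practical protocol
grows plants in a large (36 in × 36 in × 60 in) growth volume containing a
regular internal scaffold — PVC frame plus a 4-inch-pitch line grid at ten
depths — so the root system can be excavated intact, photographed, and
reconstructed as a colored 3D point cloud by structure-from-motion
photogrammetry. The scaffold then serves triple duty: it is a coordinate
reference for registering the cloud, a dissection grid for ground-truthing
against per-cell biomass, and a spatial index for relating root placement to
buried-sensor measurements of soil moisture, temperature and CO₂.

`rhizocloud` implements that downstream computational pipeline:

| Module | Role |
| --- | --- |
| `cloudio` | PLY point-cloud and long-format sensor-CSV I/O; coordinate conventions |
| `scaffoldseg` | Similarity (Procrustes) registration to the scaffold frame; scaffold, dye-noise and outlier removal via CIELAB color rules |
| `traits` | Convex hull, PCA shape ratios, alpha-shape volumes, solidity, depth-resolved profiles, root:shoot ratio |
| `rootskel` | Laplacian-contraction curve skeletonization and total root length |
| `cuboid` | 9×9×10 cuboid dissection grid (810 cells), relative distributions, R² against biomass, occupancy labels |
| `envflux` | Boundary-augmented Delaunay interpolation of the 14-sensor array; root/non-root stratified layer means |
| `synthroot` | Labeled synthetic mesocosm clouds and geometric phantoms with recorded ground truth |
| `cli` | `rhizocloud` command-line pipeline |

All geometry is in inches in the "aligned" frame: origin at a top scaffold
corner, x/y spanning the 36-inch interior, z measuring depth downward from
the media surface to 60 in.

## Worked example

Generate a labeled synthetic mesocosm cloud, segment it, and compute traits
(numbers below are the actual output for seed 1):

```python
from rhizocloud import (
    SyntheticRootParams, simulate_root_cloud, build_scaffold_geometry,
    segment_root_cloud, compute_trait_report,
    build_cuboid_grid, assign_points_to_cuboids,
    relative_distribution, distribution_r_squared,
)

labeled = simulate_root_cloud(SyntheticRootParams(seed=1))
len(labeled.cloud)                      # 102163 points
labeled.truth.class_counts              # {'root': 41995, 'scaffold': 59328, 'noise': 840}
labeled.truth.total_length              # 1680.4 in of constructed root centerline

root, log = segment_root_cloud(labeled.cloud, build_scaffold_geometry())
log   # {'input': 102163, 'scaffold_removed': 59333, 'blue_removed': 840,
      #  'outliers_removed': 1315, 'output': 40675}

report = compute_trait_report(root, root_dry_weight=52.9, shoot_dry_weight=44.5)
d = report.to_dict()
d["convex_hull_volume_in3"]             # 17725.4
d["alpha_volumes_in3"]["2.0"]           # 1796.0
d["solidity"]                           # 0.101
d["root_shoot_ratio"]                   # 1.19

grid = build_cuboid_grid()              # 810 cells, 4×4×6 in each
counts = assign_points_to_cuboids(labeled.points_of("root").coords, grid)
distribution_r_squared(
    relative_distribution(counts), labeled.truth.cuboid_fractions
)                                       # 1.0 (counts vs. generator truth)
```

Against the generator's labels this segmentation scores precision 1.000 and
recall 0.969.

The same pipeline from the command line:

```sh
rhizocloud simulate --seed 1 --out synthetic/
rhizocloud run --cloud synthetic/cloud.ply --sensors synthetic/sensors.csv --out report/
# report/report.json holds segmentation counts, total skeleton length,
# the trait report, grid summary and stratified sensor-layer means.
```

Skeleton length on geometric phantoms (a 50-inch tube and a Y-branch of
total length 50 in) is recovered within 5 % of constructed truth; see
`docs/methods.md` for accuracy characteristics and known limitations on
dense full-system clouds.

## Reproducing results

`scripts/acceptance.py` regenerates every headline quantity from scratch for
a given seed and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Each entry is `{"value": <number>, "n": <sample size>}` — structural
constants (14 sensors, 21 added boundary points, 35 support points, 810
cuboids), exactness residuals (similarity-transform recovery, affine-field
interpolation, alpha-shape versus convex hull), color-space anchors, the
seven published root:shoot ratios, synthetic-cloud segmentation
precision/recall, and phantom skeleton-length error. The run takes well
under a minute and reads nothing outside the repository.

The full test suite (`tests/`, including `tests/test_acceptance.py`, which
encodes the acceptance criteria one test per criterion) runs in a few
minutes on one CPU:

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

## Documentation

- `docs/methods.md` — models, algorithms, parameter defaults and rationale,
  numerical choices, and known limitations.
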