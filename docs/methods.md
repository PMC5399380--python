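# Methods

## The statistic

A spheroid imaged as a nuclear-stain z-stack is reduced to one number,
the cell/body volume ratio ρ = V_cell / V_body. Both volumes come from
alpha complexes (circumradius formulation: the union of Delaunay
tetrahedra whose circumsphere radius is ≤ α) built over the same point
cloud of foreground voxel centres:

* **V_cell** uses α_cell = `cell_factor` × max(dz, dy, dx). The default
  `cell_factor = 3` (α_cell = 6 µm at the default pitch) bridges
  adjacent nuclei within a cell layer — inter-nucleus gaps in a
  confluent epithelium are a few µm — but cannot span a lumen of
  diameter ≫ α, so the cavity is excluded.
* **V_body** uses α_body = `body_factor` × max pitch with
  `body_factor = 1e6`, i.e. effectively the convex hull: the spheroid
  body by definition spans the lumen.

For an ideal hollow shell of outer radius R and lumen radius r,
ρ = 1 − (r/R)³; for a filled lumen ρ → 1. Monotonicity of the alpha
complex in α guarantees ρ ≤ 1. Volumes are sums of tetrahedron
determinant volumes (robust to non-manifold unions); no surface-mesh
integration is attempted.

Two alphas from one cloud is a deliberate reading: a single alpha cannot
produce two distinct volumes from the same points, and "cell" vs "body"
is exactly the distinction between an alpha that respects cavities and
one that does not.

## Pipeline stages and their parameters

| stage | parameter | default | why |
|---|---|---|---|
| threshold | method | `otsu` | canonical histogram-profile rule; `mean` / `percentile` swappable in config |
| histogram | bins | 256 (8-bit) / 65 536 (16-bit) | native intensity resolution |
| clustering | `eps_um` | 2 × max pitch (4 µm) | must bridge the largest inter-slice gap of an anisotropic stack |
| clustering | `min_points` | 10 | isolated detector-noise voxels have far fewer neighbours |
| subsampling | `max_points` | 200 000 | keeps Delaunay/DBSCAN desk-scale; uniform without replacement, seeded |
| geometry | `cell_factor` | 3 | see above |
| geometry | `body_factor` | 1e6 | effectively convex hull |

Binarisation is a strict `intensity > threshold` comparison. Thresholds
are computed per stack by default; a pooled-histogram mode (one global
threshold across an experiment) is available via `pooled_histogram` —
per-stack is the default because illumination varies between gels.
No morphological clean-up is applied after thresholding; noise rejection
is delegated entirely to the clustering stage.

Axis order is (z, y, x) everywhere, pitch is (dz, dy, dx) µm, and
physical coordinates use voxel centres ((i + 0.5)·pitch). A stack
without a pitch source (override, sidecar JSON, OME metadata) is an
error, never a silent default.

DBSCAN runs in physical µm space through scikit-learn; border points are
assigned deterministically in data order, and main-cluster ties break to
the lowest label. ANOVA is the classical fixed-effects decomposition
(scipy); Tukey q values and adjusted p are computed from MS_within and
the studentized-range distribution, with the Tukey–Kramer harmonic
correction for unequal group sizes. Zero within-group variance with
unequal means is reported as F = ∞, p = 0 and flagged, rather than
raising. Each spheroid is one observation; grouping columns are kept in
the results so users can re-aggregate by gel or donor.

## The phantom generator

`generate_phantom` emulates a DAPI-labelled duct spheroid in a confocal
stack:

* **Geometry.** Nuclei are solid balls of radius 3.5 µm (human
  epithelial nuclei are ~7–10 µm across). Shell nuclei centres are
  rejection-sampled uniformly in the spherical shell
  [r, R − r_nucleus]; the default count of 100 follows a Poisson-
  coverage packing argument targeting ~50 % nuclear volume fraction in
  the shell (n = V_shell·ln 2 / v_nucleus), i.e. a confluent bilayer.
  Defaults R = 20 µm, r = 12 µm match a small duct spheroid.
* **Filling.** When `fill_fraction > 0`, nuclei are dropped uniformly in
  the whole lumen ball until the voxel-counted occupied lumen volume
  reaches `fill_fraction` × lumen volume. Centres may sit anywhere in
  the lumen (not only ≥ one nucleus radius from its boundary): filled
  lumina pack cells against the shell, and restricting centres would
  make `fill_fraction = 1` unreachable by random covering. Placement is
  bounded; exceeding the bound raises a `PlacementError`.
* **Optics and noise.** The binary occupancy is rendered at
  `fg_intensity`/`bg_intensity` (200/20), blurred by an isotropic
  Gaussian PSF (σ = 0.5 µm) and corrupted with additive Gaussian read
  noise (SD 10), then clipped at zero. Poisson shot noise, spectral
  bleed-through and depth-dependent attenuation are deliberately out of
  scope — the threshold stage is exercised separately for robustness.
* **Sampling grid.** Default pitch (dz, dy, dx) = (2.0, 0.5, 0.5) µm and
  stack shape (32, 128, 128): typical confocal anisotropy with the
  sphere plus one nucleus diameter of margin inside the stack.
* **Ground truth.** `GroundTruth` carries the closed-form volumes
  (V_body = 4/3·πR³, ρ = 1 − (1 − f)(r/R)³) plus
  `rendered_cell_volume_um3`, the voxel-union volume actually drawn —
  the quantity the segmentation stage can recover exactly. Everything is
  a pure function of (spec, seed).

**What passing phantom tests does and does not show.** The phantoms
validate the geometry chain — thresholding, physical scaling, cluster
isolation, alpha volumetrics — under known ground truth. They do not
model uneven staining, nuclear texture, z-attenuation or touching
spheroids, so performance on real stacks still depends on acquisition
quality; the per-stack Otsu threshold and the DBSCAN stage are the
components that absorb most real-data variation.

**Known bias.** Nuclei sample the shell stochastically, so the convex
hull slightly under-reaches R (few nucleus tips touch the outer
boundary in any one direction) and the cell alpha shape leaves small
un-bridged pockets; both volumes are biased low by ~5 %, partially
cancelling in ρ. Recovered hollow-shell ratios centre ~0.76–0.77
against the analytic 0.784 (mean absolute error ≈ 0.02); filled-lumen
ratios centre ~0.90 rather than 1.0, dominated by the hull-vs-alpha
boundary mismatch. Group separations of interest (Δρ ≈ 0.14) are an
order of magnitude above this bias.

## Numerical choices

* Otsu maximisation is over histogram bin centres; ties break to the
  lowest maximising threshold, so results are deterministic.
* Tetrahedron circumradii solve the 3×3 circumcentre system per simplex,
  vectorised; singular (flat) simplices get radius ∞ and are never
  retained.
* Rank-deficient (coplanar/collinear) clouds yield volume 0 with a
  warning; a full-rank cloud that still breaks Qhull is retried once
  with a deterministic 1e-9 × pitch jitter.
* Uniform scaling of coordinates and alphas by s scales volumes by s³
  exactly (the Delaunay triangulation is scale-invariant), which is the
  basis of the scaling-law check.
* Per-phantom seeds in simulated experiments derive from a
  `SeedSequence` of the experiment seed, keeping every value below 2³¹.

## Test and validation problem sizes

Unit tests run on reduced phantoms (R = 14 µm, lumen 9 µm, ~0.1 s each);
the lumen diameter is kept well above α_cell so the cavity geometry is
representative. End-to-end validation uses the full default conditions:
20 hollow + 6 filled spheroids for ratio recovery, a 3 × 6 experiment
for the discrimination test, 50–100 random instances for each oracle
cross-check, and 1 000 null datasets for ANOVA type-I calibration.

## Limitations

* One spheroid per stack is assumed (the largest cluster wins); touching
  spheroids of similar size would need seeded splitting.
* No per-nucleus instance segmentation or cell counting — the method is
  purely volumetric.
* The two alpha factors are resolution multiples, not optimised per
  dataset; grossly different acquisition geometries may need re-tuning
  via config.
* Statistics mirror the fixed-effects ANOVA + Tukey procedure only; no
  mixed-effects modelling of donor or gel.
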