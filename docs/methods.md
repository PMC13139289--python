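# Methods

This note documents the models, numerical choices and known limitations of
`calcmorph`.  It is written for users who need to judge what the package's
validation on synthetic data does — and does not — establish about real
scans.

## Geometry conventions

Volumes are 3D grids of Hounsfield units with positive, axis-aligned
spacing: world position of voxel `(i, j, k)` is `origin + index * spacing`.
Oblique or flipped affines are rejected on read rather than silently
resampled; the intended acquisition is an axial head CT.  Masks share a
reference volume's geometry to within 1e-4 mm.

Resampling maps the new grid onto the old one with the output grid aligned
to the original origin; HU volumes use linear interpolation, masks
nearest-neighbor (they remain strictly binary).  Two consequences worth
knowing: resampling to the original spacing is the identity, and at an
exact integer factor the coarse samples coincide with fine voxel centers,
so "linear" down-sampling degenerates to decimation.  Alternatives
(cell-centered trilinear, local-mean, median-block) were evaluated and
rejected: every mean-like kernel couples the fixed 130 HU threshold to the
deposit's HU — a voxel becomes "calcified" at a fill fraction of
`(130 − lumen HU)/(deposit HU − lumen HU)`, inflating volumes by an amount
that depends on contrast rather than geometry.  Decimation is noisier but
nearly unbiased (−3% on phantom ensembles vs +25% for trilinear).

## Segmentation

Calcified voxels are those with HU in `[130, 500]` (both bounds inclusive)
inside the artery label.  130 follows the Agatston convention; 500
excludes bone that the artery label cannot reliably avoid.  Whether 500
itself is calcified is not settled by convention; the bound is inclusive
here and configurable.  No minimum component size is imposed by default —
single-voxel deposits count; an opt-in filter exists in
`MorphometryConfig.min_component_voxels`.

## Surface modeling

Marching cubes at iso-level 0.5 on the binary field (zero-padded by one
voxel so boundary-touching masks close), vertices mapped to world mm,
winding repaired to consistent outward orientation.  Raw marching-cubes
meshes of binary data carry a 45° chamfer staircase whose total area
overestimates smooth surfaces by roughly 8% *independent of resolution* —
a voxelized ball measures ~+8.5% at 1.0, 0.5 and 0.25 mm alike.  The mesh
is therefore smoothed with a volume-preserving Taubin pass whose iteration
count scales as `round(10 · (0.5 mm / spacing)²)`: the smoothing window is
then a fixed physical width (~1.6 mm), the staircase is removed at every
resolution, and the measured area converges under refinement (ball:
+5.5% → +1.4% → +0.3% across 1.0/0.5/0.25 mm; annulus shell:
+2.6% → +1.8% → +0.4%).  Meshes with fewer than 100 faces are left
unsmoothed: at that size Taubin collapses the mesh (a single voxel's
octahedron shrinks by ~95%) instead of de-aliasing it, so voxel-scale
specks keep their raw marching-cubes area (√3 · spacing² for one voxel).

`S` is the sum of triangle areas over all components of a participant's
calcification, pooled across sides.

## Thickness estimation

For face `i` with unit normal **A**, candidates are all faces `j ≠ i`
whose normal **B** satisfies **A·B** < 0, strictly — at exactly 90° the
faces are not opposing.  `T(i)` is the minimum centroid-to-centroid
distance over candidates; faces with no candidate (open sheets) are
flagged missing.  The defining algorithm is the exhaustive O(F²) double
loop; the production path queries a KD-tree in increasing distance order
and is exactly equivalent (the first opposing neighbor in distance order
attains the minimum), which the test suite verifies face-by-face against
the double loop on random phantoms.

### Radial weighting

Each calcification face is compared against its k = 5 nearest faces on the
artery surface model (nearest by centroid distance; ties broken by lowest
face index for determinism).  With θ̄ the mean angle between the face
normal and those artery-face normals, the weight is `w = |cos θ̄|` — 1 when
the face looks across the vessel cross-section (θ̄ → 0° or 180°), 0 when it
looks along the axis (θ̄ → 90°).  The cosine form is the simplest smooth,
parameter-free function with those limits.

### Representative T

The participant-level summary is the weighted 97th percentile of the
per-face field, pooling faces across components and sides before taking
the quantile (pooling is the only order-independent choice when a
participant has several deposits).  Weights enter as frequency weights in
a cumulative-weight quantile with linear interpolation between order
statistics — positions `p_i = (S_i − w_i)/(S_n − w_n)` for the sorted
values — which reduces exactly to the ordinary linear-interpolation
percentile at uniform weights.  Treating `w` as an inclusion weight (near
zero ⇒ effectively excluded) rather than scaling `T` by `w` keeps the
summary in mm and matches the weighting's purpose of restricting the
estimate to cross-sectional measurements.  Participants with no calcified
voxels get `S = 0`, volume 0, `T = 0` and an explicit flag, so cohort
tables carry no missing morphometry.

### Behavior on voxelized vs idealized surfaces

On voxelized phantoms the estimator is strongly self-stabilizing: residual
normal jitter from the triangulation gives edge faces (deposit end caps,
arc cuts) nearby partners with slightly opposing normals, so their `T` is
small rather than the deposit length, and the 97th percentile recovers the
wall thickness within one voxel even *without* weighting.  The failure
mode the weighting corrects is visible in its pure form on idealized
(analytically meshed) shells with exact normals: there the flat end faces
pair only across the deposit (`T` = length), the unweighted 97th
percentile reads the deposit length, and the weighted one recovers the
wall.  Validation therefore uses voxelized phantoms for recovery accuracy
and the idealized half-arc shell for the weighting contract.  On real
surface models — which are voxelized — the practical effect of the
weighting lies between these extremes.

## Phantoms

Phantoms voxelize continuous shapes (annular shell sector, slab, spherical
shell) by the voxel-center rule, with the shape center offset from the
grid by spacing/3 so that round-number boundaries fall generically between
sample points (an aligned grid would otherwise include or exclude whole
boundary planes at once).  Default HU: calcification 300 (configurable
within the calcium window), lumen 40, background 0, and a 1000 HU bone
block adjacent to but outside the artery mask, exercising the upper window
bound.  The artery tube extends 1 mm radially and 2 mm axially beyond the
calcification, as a real vessel label would continue past a deposit.

The cohort fixture draws right-skewed wall thicknesses spanning 1–3.5 mm,
arcs 90–360°, and sizes giving a right-skewed volume distribution with
mean near 54 mm³ — the scale reported for intracranial carotid deposits in
vivo.  What the phantoms deliberately lack: scanner point-spread blur,
noise, beam hardening, and curved (siphon-shaped) artery geometry.
Passing phantom tests therefore demonstrates geometric correctness of the
pipeline, not robustness to acquisition physics.

One consequence is worth stating plainly: because the phantoms'
piecewise-constant HU lets thresholding recover the ground-truth mask
*exactly* (a property the segmentation tests rely on), their HU field is
not band-limited, and down-sampling such a field to 1.25 mm aliases — the
per-phantom volume error (~15%) is several times what smooth, PSF-blurred
clinical data show, and the cross-resolution Pearson correlation measures
0.96–0.98 on 50-phantom ensembles rather than the near-perfect agreement
achievable on real scans.  The two desiderata (exact threshold recovery
and resolution-stable volumes) are physically incompatible in one phantom.

## Synthetic cohorts and regression

Cohorts are generated with log-normal S and T margins calibrated so the
median/IQR match the targets (62.75/193.35 mm² and 1.07/0.60 mm by
default), tied to a piecewise-uniform age distribution over the study's
decade weights by a Gaussian copula (latent Pearson `2·sin(π·ρ_s/6)` from
the Spearman targets: age–S 0.64, age–T 0.55, S–T 0.862).  A 35/1232
fraction — the participants with the least latent calcification — is set
to S = T = 0.  Regional volumes are linear in the z-scored *observed*
predictors plus Gaussian noise, so OLS on the generated table recovers the
specified standardized effects without bias; recovery runs at n = 1232 over
200 replicates show |bias| < 0.005 and 95%-CI coverage ≈ 94–95%.

Modeling conventions: z-scoring uses the sample SD (n−1); sex and
population enter as unstandardized 0/1 indicators; β* comes from the fully
standardized fit (and equals β·SD(x)/SD(y)); p-values are two-sided t
tests at n−k−1 degrees of freedom; the BH-FDR family is per model and per
predictor across regions (configurable by calling `bh_adjust` directly on
any other family).  VIF is `1/(1−R²)` of each predictor regressed on the
others; perfect collinearity raises rather than reporting infinity.

## Known limitations

- `T` does not distinguish inward (lumen-narrowing) from outward growth:
  the artery label contains both the wall and the luminal space.
- Thickness precision is bounded by voxel spacing; sub-voxel walls
  (below ~1 voxel) are in a warned, unsupported regime.
- The candidate rule uses only the dot-product sign; no constraint keeps
  the partner near the normal ray, which is faithful to the definition but
  means `T` on highly non-convex deposits can reflect cross-lobe
  distances.
- Cross-resolution volume agreement on synthetic phantoms understates what
  smooth clinical data achieve (see above).
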