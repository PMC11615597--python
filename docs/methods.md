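# Methods

## Problem and scope

The package measures vessel-wall motion of the thoracic aorta from a 4D
binary segmentation series: one 3D mask per cardiac phase on a common
voxel grid (the study regime it targets is 15 phases at 1.6 mm isotropic
resolution).  It does not acquire, reconstruct, or segment images — masks
may come from any source (deep-learning segmentation, manual contouring).
All downstream quantities are defined on the triangulated surface of the
vessel at the end-diastolic reference phase, which is by convention the
first timeframe.

## Surface extraction

Masks are binarized at 0.5, zero-padded (so surfaces close at the grid
border), Gaussian-smoothed with σ = 0.5 voxel, and meshed by marching
cubes at iso-level 0.5; the result is Taubin-smoothed (λ = 0.5,
μ = −0.53, 10 iterations).  Both smoothing steps exist to suppress the
voxelization staircase, which would otherwise bias ray-cast diameters;
Taubin (rather than Laplacian) smoothing is used because it is
volume-preserving to first order (< 2% volume change on a rasterized
ball).  Vertices are mapped to world mm through the NIfTI affine (voxel
centers, RAS+).  Outward unit normals are area-weighted face-normal
averages, with winding flipped if the enclosed signed volume is negative.

Degenerate inputs: a surface with several connected components keeps only
the largest (satellite components are treated as segmentation noise, with
a warning); a structure too small for the smoothed field to reach the
iso-level (a sub-voxel blob) is meshed on a 4× block-upsampled copy
instead, and meshes with fewer than 50 vertices skip Taubin smoothing,
which would collapse them toward their centroid.

## Non-rigid surface registration

The reference mesh is registered **directly** to each other phase (never
chained frame-to-frame, so phases are independent and any one failure is
contained).  Registration is an iterative global deformation by Gaussian
radial basis functions:

* **Schedule.** Over 30 iterations, factor k₁ rises linearly 1 → 1.5 and
  k₂ falls 3 → 1.5.  Iteration *i* uses N_c = round(10·k₁) deformation
  centers and kernel width γ = max(k₂ · 2 · D_mean, γ_floor), where
  D_mean is the current mean distance from warped-source vertices to the
  target surface.  Early iterations therefore apply few, wide kernels
  (bulk motion); late ones more, narrower kernels (local wall motion).
  The floor γ_floor = 2 × voxel spacing stops the width collapsing below
  what the mesh resolves.  Both formulas admit an alternative reading
  with k₁, k₂ as exponents; `GRBFConfig.nc_rule = "power"` and
  `gamma_rule = "reciprocal"` switch to those, and all endpoints are
  plain config fields.
* **Centers.** Farthest-point sampling over the current warped vertices,
  re-selected every iteration (the schedule changes N_c).  The start
  point is the lowest-index vertex nearest a seeded random location in
  the bounding box, so center selection is deterministic for a fixed
  seed.
* **Solve.** Correspondences are source-vertex → closest point on the
  target *surface* (not vertex-to-vertex: meshes of different phases have
  unrelated vertex counts).  Per-center displacement weights are fitted
  to the residual vectors by damped least squares, with ridge term
  `damping × trace(KᵀK)/N_c · I` (default damping 1e-6); the kernel
  matrix is ill-conditioned for large γ and the damping keeps the solve
  finite without visibly biasing the fit.
* **Initialization.** Before the schedule, a translation-only
  iterative-closest-point alignment runs to convergence (step < 1e-4 mm,
  cap 100 iterations).  This step is essential for measuring bulk motion
  correctly: closest-point residuals applied as a non-rigid field allow
  vertices to slide tangentially onto the target, so without it a rigid
  2 mm shift of a sphere is recovered as only ~1.2 mm mean displacement.
  With it, the same experiment recovers 2.000 mm.  The alignment is
  translation-only by design — rotation about a near-cylindrical vessel's
  axis is unobservable from its surface, and a fitted rotation could only
  inject spurious tangential displacement.  `rigid_init=False` disables
  it.

The per-iteration D_mean trace is recorded; on every test fixture the
final entry is at most the first (the registration may not worsen the
fit overall).  All state (warped vertices, centers, weights, trace) is
serializable, and the whole procedure is bit-deterministic for fixed
inputs and seed.

## Motion maps

* **Displacement** — ‖warped_v − reference_v‖₂ per reference vertex.
* **Diameter** — per phase, independently: from each vertex a ray is cast
  along the inward normal; the distance to the first triangle hit farther
  than ε = 0.5 mm (a guard against grazing self-hits at the origin
  vertex) is the diameter.  Rays without a hit within 60 mm (e.g.
  escaping through branch ostia or open rims) are flagged invalid and
  excluded from aggregates rather than imputed, which would bias ROI
  means.  Both lengths are configurable.
* **Diameter change** — each reference vertex's registered position is
  projected onto the target surface; the target diameter there is
  interpolated barycentrically (the minimal smooth choice on a triangle
  mesh) and compared with the vertex's reference diameter, in mm and as a
  percentage of the reference diameter.  The comparison is between the
  *measured* target-phase diameter and the carried reference diameter —
  not a re-measurement on the warped reference mesh — so diameter error
  does not compound with registration error.

ROI summaries use a static axis-aligned box defined on the reference
phase.  Reference-indexed maps (displacement, change) evaluate membership
once at reference positions and reuse it for all phases — a vertex that
moves out of the box at systole still counts.  Per-phase diameter maps
evaluate membership at that phase's own vertex positions against the same
box.  Phase-0 displacement and diameter change are exactly zero by
construction.

## Statistics

Group curves are summarized per phase as median and IQR (Q3 − Q1, linear
interpolation between order statistics — the most common convention; the
Q1/Q3 interval is also reported).  Paired method agreement uses Pearson
correlation and Bland–Altman limits of agreement (differences are
first-minus-second; LOA multiplier fixed at 1.96, SD with ddof = 1),
gated by a Shapiro–Wilk normality check that warns rather than aborts.
Test–retest–rescan repeatability is the maximum over phases of the
across-scan range (max − min of the three scans).  Dice overlap and the
area-equivalent diameter DA = 2·√(Area/π) round out the toolbox.

## Synthetic phantom

The phantom emulates the target data regime: a curved tube — straight
segment (60 mm) joined to a half-torus arch (radius 30 mm) — of baseline
radius 12.5 mm, rasterized at 1.6 mm isotropic over 15 phases.  Motion is
rigid bulk translation (default (9, 0, 9) mm, ‖·‖ ≈ 12.7 mm) plus uniform
radial distension (amplitude 0.7 mm, i.e. 1.4 mm peak diameter change),
both scaled by a shared waveform w(t): a raised-cosine upstroke from 0 at
end-diastole to 1 at peak systole (phase 5 of 15), then an exponential
decay onto a mid-level plateau with a cosine taper back toward zero.
These magnitudes place the phantom in the scale regime reported for the
healthy ascending aorta (~25 mm diameter, up to ~13 mm peak displacement,
~1.4 mm systolic diameter change); they are design targets for the
generator, not reproduced results.

Voxel membership is by voxel-center distance to the centerline (exact for
both the straight segment and the torus arc; no partial volume), matching
the binary-mask input contract.  The centerline is tilted by (9°, 7°)
about the grid's x and y axes by default: a perfectly grid-aligned tube
is a degenerate rasterization case in which voxel membership changes in
discrete jumps and sub-voxel radius changes can vanish from the masks
entirely; a few degrees of tilt dithers the sampling the way any real
vessel orientation does.  Ground truth is analytic: diameter 2·(r₀ +
amp·w(t)) exactly, and per-phase surface-displacement statistics from the
vector sum of translation and radial distension over a dense analytic
surface sampling.

What the phantom does **not** emulate: segmentation noise, partial-volume
effects, branch vessels, wall shear or elongation, through-plane
twisting, and imaging artifacts.  Passing the phantom suites shows the
geometry pipeline recovers known motion at study scale; it does not
certify performance on noisy clinical segmentations.

## Problem sizes and numerical choices

Validation suites run the full pipeline on phantoms of ~40–90k voxels per
phase (meshes of roughly 4–8k vertices), 15 phases, chosen so each suite
completes in minutes on a single CPU.  Geometry queries (closest point on
surface, ray casting) are exact, vectorized, and deterministic: closest
points via a KD-tree broad phase over triangle centroids (plus triangles
incident to the nearest vertex) with exact point-triangle projection, ray
casting via a compiled Möller–Trumbore kernel.  Quantile computations use
NumPy's linear-interpolation convention; Shapiro–Wilk on exactly constant
differences is reported as p = 1 (no evidence against normality) rather
than an error.  Ties in farthest-point sampling break to the lowest
vertex index.

## Known limitations

* Displacement from surface registration is only as observable as the
  surface geometry allows: motion tangential to a locally symmetric
  surface (e.g. rotation about a straight tube's axis) is invisible in
  principle; the translation-only ICP initialization recovers bulk
  translation, but non-rigid tangential sliding within the G-RBF stage
  is not separately constrained.
* The ROI is a user-supplied static box; no anatomical landmarks are
  detected.
* Diameter by inward-normal ray casting assumes a roughly tubular local
  geometry; at high-curvature regions (inner arch) the chord measured is
  not guaranteed to be the minimal cross-sectional diameter.
* Masks are consumed as-is: no topology repair beyond
  largest-component selection.
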