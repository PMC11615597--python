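# aortamotion

Quantify three-dimensional aortic wall motion over the cardiac cycle from
time-resolved binary segmentations.

Free-running 3D cine MRI of the thoracic aorta can be segmented into one
binary mask per cardiac phase (typically 15 phases at 1.6 mm isotropic
resolution).  `aortamotion` turns such a 4D mask series into per-vertex
**displacement**, **diameter**, and **diameter-change** maps of the vessel
surface, and summarizes them as per-phase motion curves inside a
user-defined region of interest (for the ascending aorta: a static
bounding box from the sinotubular edge to the mid-arch).  It is aimed at
researchers studying aortic distensibility and bulk motion — e.g. for
radiotherapy planning margins or connective-tissue disease follow-up —
who already have segmentations from any source and need reproducible
motion metrics plus the accompanying agreement and repeatability
statistics.

## Method

1. **Surface extraction** — each phase's mask is meshed by marching cubes
   at iso-level 0.5 after light Gaussian pre-smoothing (σ = 0.5 voxel),
   followed by 10 iterations of Taubin smoothing (λ = 0.5, μ = −0.53), in
   world-mm coordinates.
2. **Non-rigid registration** — the end-diastolic reference surface
   (always the first timeframe) is registered directly to every other
   phase.  After a translation-only ICP initialization, an iterative
   global deformation with N<sub>c</sub> Gaussian radial basis functions
   runs for 30 iterations.  Per iteration *i*, with factors k₁: 1 → 1.5
   and k₂: 3 → 1.5 interpolated linearly over the iterations:

   - N<sub>c</sub> = round(10·k₁) farthest-point-sampled centers,
   - kernel width γ = max(k₂ · 2 · D_mean, γ_floor), where D_mean is the
     current mean distance from warped-source vertices to the target
     surface,
   - damped least-squares fit of per-center displacement weights to
     closest-point residuals, then the smooth warp
     x ↦ x + Σ_c w_c · exp(−‖x − c‖²/γ²) is applied.

3. **Motion maps** — displacement is the per-vertex Euclidean distance
   between reference and registered positions.  Diameter is measured per
   phase by casting each vertex's inward normal to the opposite wall.
   Diameter change carries the reference diameter map through the
   registration and compares it with the target phase's diameter,
   interpolated barycentrically at the registered position (also as % of
   the reference diameter).
4. **Statistics** — group curves as median (IQR); paired method agreement
   via Pearson r and Bland–Altman bias ± 1.96·SD after a Shapiro–Wilk
   normality check; test–retest–rescan repeatability as the largest
   across-scan difference over all cardiac phases; Dice overlap for
   segmentation comparison; area-equivalent diameter DA = 2·√(Area/π).

A synthetic phantom module generates 4D series of a pulsating, translating
curved tube ("candy cane") with analytic ground truth for validation.

## Worked example

```python
import numpy as np
from aortamotion import GRBFConfig, PhantomSpec, RoiBox, generate_phantom, run_motion_analysis
from aortamotion.phantom import _centerline_points

spec = PhantomSpec()                # 25 mm tube, 0.7 mm distension, 12.7 mm bulk motion
series, gt = generate_phantom(spec)

line = _centerline_points(spec) @ spec.rotation.T   # ROI over the straight segment
seg, r = line[:160], spec.r0_mm + spec.amp_mm
roi = RoiBox(tuple(seg.min(0) - r - 2 + np.minimum(spec.translation, 0)),
             tuple(seg.max(0) + r + 2 + np.maximum(spec.translation, 0)))

result = run_motion_analysis(series, roi, GRBFConfig())
print(result.curves.table.round(3).head(6).to_string(index=False))
```

prints (phase 5 is peak systole):

```
 phase  mean_displacement_mm  max_displacement_mm  mean_diameter_mm  mean_diameter_change_mm  mean_diameter_change_pct
     0                 0.000                0.000            24.992                    0.000                     0.000
     1                 1.236                2.602            25.102                    0.077                     0.338
     2                 4.415                5.006            25.492                    0.430                     1.753
     3                 8.345                9.484            26.106                    0.873                     3.530
     4                11.505               12.121            26.680                    1.205                     4.861
     5                12.718               13.538            27.004                    1.370                     5.516
```

The analytic ground truth at phase 5 is a mean displacement of 12.74 mm
(9 mm translation in x and z each, plus 0.7 mm radial distension), a mean
diameter of 27.0 mm and a diameter change of 1.40 mm — the pipeline
recovers all three well within half a voxel (0.8 mm).

The same analysis is available from the shell:

```bash
aortamotion phantom --out phantom/
aortamotion analyze --masks phantom/phantom_masks.nii.gz \
    --roi " -24,-16,-2,45,17,60" --out results/ --seed 0
aortamotion dice phantom/phantom_masks.nii.gz phantom/phantom_masks.nii.gz
aortamotion compare test.csv retest.csv rescan.csv --out variability
```

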