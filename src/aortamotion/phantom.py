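"""Synthetic 4D segmentation phantoms with analytic ground truth.

The phantom is a curved tube — a straight ascending segment joined to a
half-torus arch (a "candy cane") — rasterized on an isotropic voxel grid
over a cardiac cycle.  Its motion is rigid bulk translation plus uniform
radial distension, both scaled by a shared systolic waveform, so surface
displacement and diameter have closed forms and any recovery error is
attributable to the analysis pipeline, not the ground truth.

Defaults emulate the geometry regime of free-running 3D cine aortic
imaging: 1.6 mm isotropic voxels, 15 cardiac phases, a ~25 mm diameter
vessel with ~0.7 mm systolic radial distension and bulk displacement up
to ~13 mm at peak systole.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .mask_io import SegmentationSeries, write_mask_series

#: fraction of peak distension retained on the early-diastolic plateau
PLATEAU_LEVEL = 0.35


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and motion of the synthetic pulsating tube.

    The centerline runs a straight segment of ``segment_length_mm`` along
    +z, then (unless ``arch_radius_mm`` is None) a half-torus arch of that
    radius bending over in the x-z plane.  ``r0_mm`` is the end-diastolic
    tube radius; at phase t the radius is ``r0 + amp * w(t)`` and the whole
    tube is rigidly translated by ``trans * w(t)``, with ``w`` the systolic
    waveform (0 at phase 0, 1 at ``peak_phase``).  ``grid_shape`` of None
    auto-fits the grid to the moving tube with a 4-voxel margin.

    ``tilt_deg`` rotates the whole centerline (about the x then y grid
    axes) so the tube is never exactly grid-aligned.  A perfectly aligned
    tube is a degenerate rasterization case: voxel-center membership then
    changes in discrete jumps, so sub-voxel radius changes can disappear
    entirely from the masks.  A few degrees of tilt dither the sampling
    the way any real vessel orientation does.
    """

    r0_mm: float = 12.5
    amp_mm: float = 0.7
    trans_mm: tuple[float, float, float] = (9.0, 0.0, 9.0)
    segment_length_mm: float = 60.0
    arch_radius_mm: float | None = 30.0
    peak_phase: int = 5
    n_phases: int = 15
    spacing_mm: float = 1.6
    grid_shape: tuple[int, int, int] | None = None
    tilt_deg: tuple[float, float] = (9.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0_mm <= 2.0 * self.spacing_mm:
            raise ValueError(
                f"radius under-resolved: r0 = {self.r0_mm} mm needs > 2 voxels "
                f"({2 * self.spacing_mm} mm)"
            )
        if not 0 <= self.peak_phase < self.n_phases:
            raise ValueError("peak_phase out of range")
        if self.amp_mm < 0:
            raise ValueError("amp_mm must be >= 0")
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases")

    @property
    def translation(self) -> np.ndarray:
        return np.asarray(self.trans_mm, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        """Tube-frame -> world rotation matrix from ``tilt_deg``."""
        return Rotation.from_euler("xy", self.tilt_deg, degrees=True).as_matrix()


@dataclass
class GroundTruth:
    """Analytic per-phase motion of the phantom surface.

    ``mean_displacement`` / ``max_displacement`` are statistics of the true
    surface displacement magnitude ``||w(t) * trans + w(t) * amp * n||``
    over a dense analytic sampling of the reference surface (n the outward
    radial direction); ``diameter`` is 2 * r(t) exactly.
    """

    waveform: np.ndarray
    radius: np.ndarray
    mean_displacement: np.ndarray
    max_displacement: np.ndarray

    @property
    def diameter(self) -> np.ndarray:
        return 2.0 * self.radius

    @property
    def diameter_change(self) -> np.ndarray:
        return self.diameter - self.diameter[0]

    @property
    def peak_phase(self) -> int:
        return int(np.argmax(self.waveform))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "phase": np.arange(len(self.waveform)),
                "waveform": self.waveform,
                "gt_mean_displacement_mm": self.mean_displacement,
                "gt_max_displacement_mm": self.max_displacement,
                "gt_diameter_mm": self.diameter,
                "gt_diameter_change_mm": self.diameter_change,
            }
        ).to_csv(path, index=False, float_format="%.9g")


def radius_waveform(phase: int, spec: PhantomSpec) -> float:
    """Normalized systolic waveform w(t) in [0, 1].

    Raised-cosine upstroke from 0 (end-diastole, phase 0) to 1 at
    ``peak_phase``, then an exponential decay superposed on a cosine taper
    so the curve settles onto a mid-level plateau before returning toward
    zero at the final phase.
    """
    if not 0 <= phase < spec.n_phases:
        raise ValueError(f"phase {phase} out of range [0, {spec.n_phases})")
    p = spec.peak_phase
    if phase <= p:
        if p == 0:
            return 1.0 if phase == 0 else 0.0
        return 0.5 * (1.0 - np.cos(np.pi * phase / p))
    # downstroke: u in (0, 1] from peak to final phase
    u = (phase - p) / (spec.n_phases - 1 - p)
    fast = (1.0 - PLATEAU_LEVEL) * np.exp(-4.0 * u)
    slow = PLATEAU_LEVEL * 0.5 * (1.0 + np.cos(np.pi * u))
    return float(fast + slow)


def _centerline_distance(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Exact distance from points (n, 3) to the untranslated centerline."""
    x0 = y0 = z0 = 0.0  # local frame; the grid affine positions the tube
    length = spec.segment_length_mm
    p = points
    # straight segment from (0,0,0) to (0,0,L)
    t = np.clip(p[:, 2] - z0, 0.0, length)
    d_seg = np.sqrt((p[:, 0] - x0) ** 2 + (p[:, 1] - y0) ** 2 + (p[:, 2] - z0 - t) ** 2)
    if spec.arch_radius_mm is None:
        return d_seg
    # half-torus arch in the x-z plane: circle center C, angle 0 at the
    # segment top, pi at the descending side, arc going over the top
    radius = spec.arch_radius_mm
    c = np.array([x0 + radius, y0, z0 + length])
    q = p - c
    rho = np.hypot(q[:, 0], q[:, 2])
    phi = np.arctan2(q[:, 2], -q[:, 0])  # 0 at segment top, pi/2 at apex
    on_arc = (phi >= 0) & (phi <= np.pi)
    d_arc = np.sqrt((rho - radius) ** 2 + q[:, 1] ** 2)
    end_a = c + np.array([-radius, 0.0, 0.0])  # == segment top
    end_b = c + np.array([radius, 0.0, 0.0])
    d_ends = np.minimum(
        np.linalg.norm(p - end_a, axis=1), np.linalg.norm(p - end_b, axis=1)
    )
    d_arc = np.where(on_arc, d_arc, d_ends)
    return np.minimum(d_seg, d_arc)


def _centerline_points(spec: PhantomSpec, n: int = 200) -> np.ndarray:
    """Dense tube-frame samples of the centerline, for bounding-box fitting."""
    z = np.linspace(0.0, spec.segment_length_mm, n)
    seg = np.stack([np.zeros(n), np.zeros(n), z], axis=1)
    if spec.arch_radius_mm is None:
        return seg
    radius = spec.arch_radius_mm
    c = np.array([radius, 0.0, spec.segment_length_mm])
    phi = np.linspace(0.0, np.pi, n)
    arc = c + radius * np.stack([-np.cos(phi), np.zeros(n), np.sin(phi)], axis=1)
    return np.concatenate([seg, arc])


def _auto_grid(spec: PhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid shape and affine fitting the tube plus motion with a 4-voxel margin."""
    r_max = spec.r0_mm + spec.amp_mm
    line = _centerline_points(spec) @ spec.rotation.T
    lo = line.min(axis=0) - r_max
    hi = line.max(axis=0) + r_max
    tr = spec.translation
    lo = lo + np.minimum(tr, 0.0)
    hi = hi + np.maximum(tr, 0.0)
    margin = 4 * spec.spacing_mm
    lo -= margin
    hi += margin
    shape = tuple(int(np.ceil(d / spec.spacing_mm)) + 1 for d in (hi - lo))
    affine = np.eye(4)
    affine[:3, :3] *= spec.spacing_mm
    affine[:3, 3] = lo
    return shape, affine


def _grid_affine(spec: PhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    if spec.grid_shape is None:
        return _auto_grid(spec)
    shape = spec.grid_shape
    affine = np.eye(4)
    affine[:3, :3] *= spec.spacing_mm
    # center the (untranslated) tube bounding box in the grid
    auto_shape, auto_aff = _auto_grid(spec)
    center_auto = auto_aff[:3, 3] + spec.spacing_mm * (np.array(auto_shape) - 1) / 2.0
    affine[:3, 3] = center_auto - spec.spacing_mm * (np.array(shape) - 1) / 2.0
    return shape, affine


def rasterize_tube(spec: PhantomSpec, phase: int) -> np.ndarray:
    """Binary mask of the (translated, distended) tube at one phase.

    A voxel is foreground iff its center lies within r(t) of the translated
    centerline (voxel-center membership, no partial volume).  Raises if the
    tube touches the grid border.
    """
    w = radius_waveform(phase, spec)
    r_t = spec.r0_mm + spec.amp_mm * w
    shape, affine = _grid_affine(spec)
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    # undo the bulk translation, then rotate into the tube frame
    d = _centerline_distance((world - spec.translation * w) @ spec.rotation, spec)
    mask = (d <= r_t).reshape(shape).astype(np.uint8)
    border = np.concatenate(
        [mask[0].ravel(), mask[-1].ravel(), mask[:, 0].ravel(), mask[:, -1].ravel(),
         mask[:, :, 0].ravel(), mask[:, :, -1].ravel()]
    )
    if border.any():
        raise ValueError(f"tube exits grid at phase {phase}; enlarge grid_shape")
    return mask


def _sample_reference_surface(spec: PhantomSpec, n_axial: int = 80, n_circ: int = 24):
    """Analytic sampling of the phase-0 tube wall: points and outward radial dirs."""
    # straight segment
    z = np.linspace(0.0, spec.segment_length_mm, n_axial // 2, endpoint=False)
    theta = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    zz, tt = np.meshgrid(z, theta, indexing="ij")
    normal = np.stack(
        [np.cos(tt).ravel(), np.sin(tt).ravel(), np.zeros(zz.size)], axis=1
    )
    base = np.stack([np.zeros(zz.size), np.zeros(zz.size), zz.ravel()], axis=1)
    pts = [base + spec.r0_mm * normal]
    dirs = [normal]
    if spec.arch_radius_mm is not None:
        radius = spec.arch_radius_mm
        c = np.array([radius, 0.0, spec.segment_length_mm])
        phi = np.linspace(0.0, np.pi, n_axial - n_axial // 2)
        pp, tt = np.meshgrid(phi, theta, indexing="ij")
        ring_dir = np.stack(  # unit vector from torus axis toward the tube center
            [-np.cos(pp).ravel(), np.zeros(pp.size), np.sin(pp).ravel()], axis=1
        )
        center = c + radius * ring_dir
        y_dir = np.tile([0.0, 1.0, 0.0], (pp.size, 1))
        nrm = np.cos(tt).ravel()[:, None] * ring_dir + np.sin(tt).ravel()[:, None] * y_dir
        pts.append(center + spec.r0_mm * nrm)
        dirs.append(nrm)
    rot = spec.rotation
    return np.concatenate(pts) @ rot.T, np.concatenate(dirs) @ rot.T


def generate_phantom(spec: PhantomSpec) -> tuple[SegmentationSeries, GroundTruth]:
    """All-phase mask series plus the analytic ground-truth motion."""
    shape, affine = _grid_affine(spec)
    masks = np.stack([rasterize_tube(spec, t) for t in range(spec.n_phases)])
    series = SegmentationSeries(masks, affine)

    wave = np.array([radius_waveform(t, spec) for t in range(spec.n_phases)])
    pts, dirs = _sample_reference_surface(spec)
    disp_mean, disp_max = [], []
    for w in wave:
        vec = w * spec.translation[None, :] + w * spec.amp_mm * dirs
        mag = np.linalg.norm(vec, axis=1)
        disp_mean.append(float(mag.mean()))
        disp_max.append(float(mag.max()))
    gt = GroundTruth(
        waveform=wave,
        radius=spec.r0_mm + spec.amp_mm * wave,
        mean_displacement=np.asarray(disp_mean),
        max_displacement=np.asarray(disp_max),
    )
    return series, gt


def write_phantom(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[SegmentationSeries, GroundTruth]:
    """Generate and write the phantom series (NIfTI), ground truth (CSV) and spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, gt = generate_phantom(spec)
    write_mask_series(series, out / "phantom_masks.nii.gz")
    gt.to_csv(out / "ground_truth.csv")
    (out / "phantom_spec.json").write_text(json.dumps(asdict(spec), indent=2))
    return series, gt
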