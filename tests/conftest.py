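import numpy as np
import pytest
import trimesh

from aortamotion.mask_io import SegmentationSeries
from aortamotion.meshing import SurfaceMesh, compute_outward_normals
from aortamotion.motion import RoiBox
from aortamotion.phantom import PhantomSpec, _centerline_points, generate_phantom


def surface_from_trimesh(tm: trimesh.Trimesh) -> SurfaceMesh:
    return compute_outward_normals(SurfaceMesh(tm.vertices.copy(), tm.faces.copy()))


def icosphere(radius: float, subdivisions: int = 3) -> SurfaceMesh:
    return surface_from_trimesh(trimesh.creation.icosphere(subdivisions, radius=radius))


def closed_cylinder(radius: float, height: float, n_z: int = 21, n_theta: int = 48) -> SurfaceMesh:
    """Finely faceted capped cylinder along z, centered at the origin."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-height / 2, height / 2, n_z)
    ring = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
    verts = [np.column_stack([np.tile(ring, (n_z, 1)), np.repeat(z, n_theta)])]
    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c, d = a + n_theta, b + n_theta
            faces += [[a, b, d], [a, d, c]]
    bot, top = n_z * n_theta, n_z * n_theta + 1
    verts.append([[0, 0, -height / 2], [0, 0, height / 2]])
    for j in range(n_theta):
        a, b = j, (j + 1) % n_theta
        faces.append([bot, b, a])
        a, b = (n_z - 1) * n_theta + j, (n_z - 1) * n_theta + (j + 1) % n_theta
        faces.append([top, a, b])
    return surface_from_trimesh(
        trimesh.Trimesh(np.concatenate(verts), np.asarray(faces), process=False)
    )


def ball_series(radius_mm: float, spacing_mm: float = 1.6) -> SegmentationSeries:
    """Two identical phases of a rasterized ball (voxel-center membership)."""
    n = int(np.ceil(2 * radius_mm / spacing_mm)) + 9
    idx = np.indices((n, n, n)).reshape(3, -1).T
    center = (n - 1) / 2.0
    d = np.linalg.norm((idx - center) * spacing_mm, axis=1)
    mask = (d <= radius_mm).reshape(n, n, n).astype(np.uint8)
    affine = np.diag([spacing_mm] * 3 + [1.0])
    return SegmentationSeries(np.stack([mask, mask]), affine)


def body_roi(spec: PhantomSpec, pad: float = 2.0, frac: tuple = (0.0, 1.0)) -> RoiBox:
    """Static box around (part of) the straight-segment tube body, motion included."""
    line = _centerline_points(spec) @ spec.rotation.T
    seg = line[: len(line) // (1 if spec.arch_radius_mm is None else 2)]
    lo_f, hi_f = frac
    seg = seg[int(lo_f * len(seg)) : max(int(hi_f * len(seg)), int(lo_f * len(seg)) + 1)]
    r = spec.r0_mm + spec.amp_mm
    lo = seg.min(axis=0) - r - pad + np.minimum(spec.translation, 0)
    hi = seg.max(axis=0) + r + pad + np.maximum(spec.translation, 0)
    return RoiBox(tuple(lo), tuple(hi))


@pytest.fixture(scope="session")
def small_phantom():
    """Fast-moving straight tube used by several pipeline-level tests."""
    spec = PhantomSpec(
        r0_mm=8.0,
        amp_mm=0.5,
        trans_mm=(0.0, 4.0, 0.0),
        segment_length_mm=40.0,
        arch_radius_mm=None,
        n_phases=5,
        peak_phase=2,
    )
    series, gt = generate_phantom(spec)
    return spec, series, gt


@pytest.fixture(scope="session")
def sphere10():
    return icosphere(10.0)
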