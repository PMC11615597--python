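"""Per-vertex motion maps and their ROI summaries.

Three per-vertex scalar fields are derived for every cardiac phase:

* displacement — Euclidean distance between each reference vertex and its
  registered position at that phase;
* diameter — vessel caliber along the inward surface normal, measured
  independently on each phase's own mesh by ray casting to the opposite
  wall;
* diameter change — the phase's diameter minus the reference diameter,
  compared at the location the registration carried each reference vertex
  to (also expressed as a percentage of the reference diameter).

Summaries are taken inside a static axis-aligned bounding box defined on
the reference phase (for the ascending aorta: sinotubular edge to
mid-arch).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import SurfaceQuery, ray_cast_first_hit
from .meshing import SurfaceMesh
from .registration import RegistrationState

#: ray-casting defaults, mm
MAX_RAY_MM = 60.0
SELF_HIT_EPSILON_MM = 0.5

VALID_KINDS = ("displacement", "diameter", "diameter_change", "diameter_change_pct")


class EmptyRoiError(ValueError):
    """Raised when an ROI box selects no vertices."""


@dataclass
class VertexMap:
    """Per-vertex scalar field with validity flags.

    ``values`` are mm for displacement/diameter/diameter_change and percent
    for diameter_change_pct; entries are meaningful only where ``valid``.
    """

    values: np.ndarray
    valid: np.ndarray
    phase: int
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}")
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")
        if not np.isfinite(self.values[self.valid]).all():
            raise ValueError("non-finite values flagged valid")

    def to_csv(self, path: str | Path, positions: np.ndarray) -> None:
        pd.DataFrame(
            {
                "vertex_id": np.arange(len(self.values)),
                "x_mm": positions[:, 0],
                "y_mm": positions[:, 1],
                "z_mm": positions[:, 2],
                "value": self.values,
                "valid": self.valid.astype(int),
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class RoiBox:
    """Static axis-aligned box in mm, defined on the reference phase."""

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.min_corner, float), np.asarray(self.max_corner, float)
        if not (lo < hi).all():
            raise ValueError("min_corner must be strictly below max_corner")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Closed-box membership for (n, 3) mm positions."""
        p = np.atleast_2d(points)
        lo, hi = np.asarray(self.min_corner), np.asarray(self.max_corner)
        return ((p >= lo) & (p <= hi)).all(axis=1)


@dataclass
class MotionCurves:
    """Per-phase ROI summaries; phase 0 is the end-diastolic reference."""

    table: pd.DataFrame  # columns: phase, mean/max displacement, diameter, change

    COLUMNS = (
        "phase",
        "mean_displacement_mm",
        "max_displacement_mm",
        "mean_diameter_mm",
        "mean_diameter_change_mm",
        "mean_diameter_change_pct",
    )

    @property
    def n_phases(self) -> int:
        return len(self.table)

    def metric(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MotionCurves":
        return cls(pd.read_csv(path))


def displacement_map(
    reference: SurfaceMesh, state: RegistrationState, phase: int
) -> VertexMap:
    """Per-vertex Euclidean displacement between reference and registered positions."""
    if len(state.warped_vertices) != reference.n_vertices:
        raise ValueError("registration state does not match the reference mesh")
    mags = np.linalg.norm(state.displacements, axis=1)
    return VertexMap(mags, np.ones(len(mags), bool), phase, "displacement")


def diameter_map(
    mesh: SurfaceMesh,
    max_ray_mm: float = MAX_RAY_MM,
    self_hit_epsilon_mm: float = SELF_HIT_EPSILON_MM,
    phase: int = 0,
) -> VertexMap:
    """Vessel diameter per vertex by casting the inward normal to the opposite wall.

    The first triangle hit farther than ``self_hit_epsilon_mm`` (guarding
    against grazing self-intersections at the origin vertex) gives the
    diameter; rays without a hit within ``max_ray_mm`` (e.g. escaping
    through branch ostia) are flagged invalid.
    """
    if mesh.normals is None:
        raise ValueError("mesh has no normals; run compute_outward_normals first")
    t, hit = ray_cast_first_hit(
        mesh.to_trimesh(),
        mesh.vertices,
        -mesh.normals,
        min_t=self_hit_epsilon_mm,
        max_t=max_ray_mm,
    )
    values = np.where(hit, t, 0.0)
    return VertexMap(values, hit, phase=phase, kind="diameter")


def transfer_diameter(
    reference_diam: VertexMap,
    state: RegistrationState,
    target_mesh: SurfaceMesh,
    target_diam: VertexMap,
) -> tuple[VertexMap, VertexMap]:
    """Diameter change (mm and %) per reference vertex at one phase.

    Each reference vertex's registered position is projected onto the
    target surface; the target diameter there is interpolated
    barycentrically and compared with the vertex's reference diameter.
    Vertices where either diameter is invalid are flagged invalid.
    """
    if len(state.warped_vertices) != len(reference_diam.values):
        raise ValueError("registration state does not match the reference diameter map")
    if len(target_diam.values) != target_mesh.n_vertices:
        raise ValueError("target diameter map does not match the target mesh")

    tm = target_mesh.to_trimesh()
    closest, _, face_idx = SurfaceQuery(tm).closest_point(state.warped_vertices)
    tri = tm.triangles.view(np.ndarray)[face_idx]
    bary = trimesh.triangles.points_to_barycentric(tri, closest)
    bary = np.clip(bary, 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)
    corner_ids = target_mesh.faces[face_idx]  # (n, 3)
    interp = (target_diam.values[corner_ids] * bary).sum(axis=1)
    corners_valid = target_diam.valid[corner_ids].all(axis=1)

    valid = reference_diam.valid & corners_valid
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.where(valid, interp - reference_diam.values, 0.0)
        pct = np.where(valid, 100.0 * change / reference_diam.values, 0.0)
    phase = target_diam.phase
    return (
        VertexMap(change, valid, phase, "diameter_change"),
        VertexMap(pct, valid, phase, "diameter_change_pct"),
    )


def roi_select(
    vmap: VertexMap, positions: np.ndarray, roi: RoiBox
) -> tuple[np.ndarray, np.ndarray]:
    """Values and validity flags of the vertices inside the (closed) ROI box.

    ``positions`` must correspond 1:1 to the map's vertices: reference-phase
    positions for reference-indexed maps (displacement, diameter change —
    membership is decided once on the reference and reused at every phase),
    or the phase's own vertex positions for per-phase diameter maps.
    """
    positions = np.atleast_2d(positions)
    if len(positions) != len(vmap.values):
        raise ValueError("positions do not correspond to map vertices")
    inside = roi.contains(positions)
    if not inside.any():
        raise EmptyRoiError("empty ROI: box selects no vertices")
    return vmap.values[inside], vmap.valid[inside]


def _roi_mean(vmap: VertexMap, positions: np.ndarray, roi: RoiBox) -> float:
    vals, ok = roi_select(vmap, positions, roi)
    if not ok.any():
        raise EmptyRoiError(f"phase {vmap.phase}: no valid {vmap.kind} values in ROI")
    return float(vals[ok].mean())


def phase_curves(
    displacement_maps: list[VertexMap],
    diameter_maps: list[VertexMap],
    change_maps: list[VertexMap],
    change_pct_maps: list[VertexMap],
    reference_positions: np.ndarray,
    phase_positions: list[np.ndarray],
    roi: RoiBox,
) -> MotionCurves:
    """Aggregate the per-vertex maps into per-phase ROI curves.

    Displacement and diameter-change maps are reference-indexed and use the
    reference vertex positions; diameter maps are evaluated on each phase's
    own mesh against the same static box.  Invalid vertices are excluded
    from the aggregates rather than imputed.
    """
    n = len(displacement_maps)
    if not (len(diameter_maps) == len(change_maps) == len(change_pct_maps) == n):
        raise ValueError("all map lists must cover the same phases")
    rows = []
    for t in range(n):
        disp_vals, disp_ok = roi_select(displacement_maps[t], reference_positions, roi)
        if not disp_ok.any():
            raise EmptyRoiError(f"phase {t}: no valid displacement values in ROI")
        rows.append(
            {
                "phase": t,
                "mean_displacement_mm": float(disp_vals[disp_ok].mean()),
                "max_displacement_mm": float(disp_vals[disp_ok].max()),
                "mean_diameter_mm": _roi_mean(diameter_maps[t], phase_positions[t], roi),
                "mean_diameter_change_mm": _roi_mean(
                    change_maps[t], reference_positions, roi
                ),
                "mean_diameter_change_pct": _roi_mean(
                    change_pct_maps[t], reference_positions, roi
                ),
            }
        )
    return MotionCurves(pd.DataFrame(rows, columns=list(MotionCurves.COLUMNS)))


def zero_reference_maps(n_vertices: int, diameter: VertexMap) -> dict[str, VertexMap]:
    """Phase-0 maps: displacement and diameter change are exactly zero by construction."""
    ones = np.ones(n_vertices, bool)
    return {
        "displacement": VertexMap(np.zeros(n_vertices), ones, 0, "displacement"),
        "diameter": diameter,
        "change": VertexMap(np.zeros(n_vertices), diameter.valid.copy(), 0, "diameter_change"),
        "change_pct": VertexMap(
            np.zeros(n_vertices), diameter.valid.copy(), 0, "diameter_change_pct"
        ),
    }
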