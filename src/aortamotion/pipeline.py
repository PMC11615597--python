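"""End-to-end motion analysis: masks -> meshes -> registration -> maps -> curves.

Every phase's mask is meshed; the end-diastolic reference (always phase 0)
is registered directly to each subsequent phase — never chained frame to
frame — and per-vertex displacement, diameter, and diameter-change maps are
summarized inside a static ROI box into per-phase curves.  A phase whose
registration fails is flagged and skipped rather than aborting the run, so
one bad frame does not cost the study.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .mask_io import SegmentationSeries
from .meshing import SurfaceMesh, extract_surface
from .motion import (
    EmptyRoiError,
    MotionCurves,
    RoiBox,
    VertexMap,
    diameter_map,
    displacement_map,
    phase_curves,
    transfer_diameter,
    zero_reference_maps,
)
from .registration import GRBFConfig, RegistrationState, register_pair

log = logging.getLogger("aortamotion")


@dataclass
class AnalysisResult:
    """All per-phase maps, registration states and summary curves of one run."""

    meshes: list[SurfaceMesh]
    displacement_maps: list[VertexMap]
    diameter_maps: list[VertexMap]
    change_maps: list[VertexMap]
    change_pct_maps: list[VertexMap]
    registration_states: list[RegistrationState | None]
    curves: MotionCurves
    failed_phases: list[int]
    provenance: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return len(self.meshes)

    def save(self, out_dir: str | Path) -> Path:
        """Write a structured results directory (curves, maps, traces, provenance)."""
        out = Path(out_dir)
        (out / "maps").mkdir(parents=True, exist_ok=True)
        (out / "registration").mkdir(exist_ok=True)
        self.curves.to_csv(out / "curves.csv")
        ref_pos = self.meshes[0].vertices
        for t in range(self.n_phases):
            self.displacement_maps[t].to_csv(
                out / "maps" / f"displacement_phase{t:02d}.csv", ref_pos
            )
            self.diameter_maps[t].to_csv(
                out / "maps" / f"diameter_phase{t:02d}.csv", self.meshes[t].vertices
            )
            self.change_maps[t].to_csv(
                out / "maps" / f"diameter_change_phase{t:02d}.csv", ref_pos
            )
            state = self.registration_states[t]
            if state is not None and state.iteration_log is not None:
                state.trace_csv(out / "registration" / f"trace_phase{t:02d}.csv")
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        return out


def run_motion_analysis(
    series: SegmentationSeries,
    roi: RoiBox,
    config: GRBFConfig | None = None,
    diameter_max_ray_mm: float = 60.0,
) -> AnalysisResult:
    """Quantify 4D vessel-wall motion of a segmentation series inside an ROI.

    Phases are registered independently from the phase-0 reference, so the
    result is invariant to processing order.  Raises :class:`EmptyRoiError`
    if the box misses the reference surface entirely.
    """
    config = (config or GRBFConfig()).resolve_gamma_floor(float(series.spacing.max()))
    log.info("meshing %d phases", series.n_phases)
    meshes = [extract_surface(series, t) for t in range(series.n_phases)]
    reference = meshes[0]
    if not roi.contains(reference.vertices).any():
        raise EmptyRoiError("ROI box does not intersect the reference surface")

    ref_diam = diameter_map(reference, max_ray_mm=diameter_max_ray_mm, phase=0)
    ref_maps = zero_reference_maps(reference.n_vertices, ref_diam)
    disp_maps = [ref_maps["displacement"]]
    diam_maps = [ref_diam]
    change_maps = [ref_maps["change"]]
    change_pct_maps = [ref_maps["change_pct"]]
    states: list[RegistrationState | None] = [None]
    failed: list[int] = []

    for t in range(1, series.n_phases):
        target = meshes[t]
        target_diam = diameter_map(target, max_ray_mm=diameter_max_ray_mm, phase=t)
        diam_maps.append(target_diam)
        try:
            state = register_pair(reference, target, config)
            log.info(
                "phase %d: D_mean %.3f -> %.3f mm",
                t, state.d_mean_trace[0], state.d_mean_trace[-1],
            )
        except FloatingPointError as exc:
            log.error("phase %d registration failed: %s", t, exc)
            failed.append(t)
            states.append(None)
            n = reference.n_vertices
            invalid = np.zeros(n, bool)
            disp_maps.append(VertexMap(np.zeros(n), invalid, t, "displacement"))
            change_maps.append(VertexMap(np.zeros(n), invalid, t, "diameter_change"))
            change_pct_maps.append(
                VertexMap(np.zeros(n), invalid, t, "diameter_change_pct")
            )
            continue
        states.append(state)
        disp_maps.append(displacement_map(reference, state, t))
        change, change_pct = transfer_diameter(ref_diam, state, target, target_diam)
        change_maps.append(change)
        change_pct_maps.append(change_pct)

    curves = phase_curves(
        disp_maps,
        diam_maps,
        change_maps,
        change_pct_maps,
        reference.vertices,
        [m.vertices for m in meshes],
        roi,
    )
    provenance = {
        "software": f"aortamotion {__version__}",
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "roi": {"min_corner": list(roi.min_corner), "max_corner": list(roi.max_corner)},
        "n_phases": series.n_phases,
        "spacing_mm": [float(s) for s in series.spacing],
        "input_sha256": hashlib.sha256(series.data.tobytes()).hexdigest(),
        "failed_phases": failed,
    }
    return AnalysisResult(
        meshes=meshes,
        displacement_maps=disp_maps,
        diameter_maps=diam_maps,
        change_maps=change_maps,
        change_pct_maps=change_pct_maps,
        registration_states=states,
        curves=curves,
        failed_phases=failed,
        provenance=provenance,
    )
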