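import numpy as np
import pytest

from aortamotion.meshing import SurfaceMesh
from aortamotion.motion import (
    EmptyRoiError,
    RoiBox,
    VertexMap,
    diameter_map,
    displacement_map,
    phase_curves,
    roi_select,
    transfer_diameter,
)
from aortamotion.registration import RegistrationState
from .conftest import closed_cylinder, icosphere


def make_state(reference: SurfaceMesh, warped_vertices: np.ndarray) -> RegistrationState:
    return RegistrationState(
        warped_vertices=warped_vertices,
        reference_vertices=reference.vertices.copy(),
        d_mean_trace=np.array([0.0]),
        centers=np.zeros((1, 3)),
        weights=np.zeros((1, 3)),
        gamma_mm=3.2,
    )


class TestDisplacementMap:
    def test_uniform_translation_three_four_five(self, sphere10):
        state = make_state(sphere10, sphere10.vertices + (3.0, 4.0, 0.0))
        vmap = displacement_map(sphere10, state, phase=1)
        assert np.allclose(vmap.values, 5.0)
        assert vmap.valid.all()

    def test_identity_zero(self, sphere10):
        state = make_state(sphere10, sphere10.vertices.copy())
        assert np.allclose(displacement_map(sphere10, state, 1).values, 0.0)

    def test_vertex_count_mismatch(self, sphere10):
        state = make_state(sphere10, sphere10.vertices[:-1])
        with pytest.raises(ValueError):
            displacement_map(sphere10, state, 1)


class TestDiameterMap:
    def test_sphere_diameter(self, sphere10):
        vmap = diameter_map(sphere10)
        assert vmap.valid.all()
        assert np.allclose(vmap.values, 20.0, atol=0.2)

    def test_cylinder_mid_height(self):
        mesh = closed_cylinder(radius=10.0, height=60.0)
        vmap = diameter_map(mesh)
        mid = np.abs(mesh.vertices[:, 2]) < 5.0
        assert vmap.valid[mid].all()
        assert np.allclose(vmap.values[mid], 20.0, atol=0.3)

    def test_open_rim_invalid(self):
        # open tube, radius 40: the opposite wall is ~80 mm away, beyond max ray
        mesh = closed_cylinder(radius=40.0, height=30.0)
        vmap = diameter_map(mesh, max_ray_mm=60.0)
        side = np.abs(mesh.vertices[:, 2]) < 10.0
        assert not vmap.valid[side].any()

    def test_missing_normals(self, sphere10):
        bare = SurfaceMesh(sphere10.vertices.copy(), sphere10.faces.copy())
        with pytest.raises(ValueError, match="normals"):
            diameter_map(bare)


class TestTransferDiameter:
    def test_zero_deformation_zero_change(self, sphere10):
        diam = diameter_map(sphere10)
        state = make_state(sphere10, sphere10.vertices.copy())
        change, pct = transfer_diameter(diam, state, sphere10, diam)
        assert np.allclose(change.values[change.valid], 0.0, atol=1e-9)
        assert np.allclose(pct.values[pct.valid], 0.0, atol=1e-9)

    def test_dilated_cylinder_change(self):
        ref = closed_cylinder(radius=10.0, height=60.0)
        tgt = closed_cylinder(radius=10.7, height=60.0)
        ref_d, tgt_d = diameter_map(ref), diameter_map(tgt)
        state = make_state(ref, ref.vertices * np.array([1.07, 1.07, 1.0]))
        change, pct = transfer_diameter(ref_d, state, tgt, tgt_d)
        body = (np.abs(ref.vertices[:, 2]) < 20.0) & change.valid
        assert change.values[body].mean() == pytest.approx(1.4, abs=0.3)

    def test_pct_consistent_with_change(self, sphere10):
        diam = diameter_map(sphere10)
        target = icosphere(11.0)
        tgt_d = diameter_map(target)
        state = make_state(sphere10, sphere10.vertices * 1.1)
        change, pct = transfer_diameter(diam, state, target, tgt_d)
        ok = change.valid
        assert np.allclose(
            pct.values[ok], 100.0 * change.values[ok] / diam.values[ok], atol=1e-9
        )

    def test_known_percentage(self):
        # reference diameter 25.0, change 1.4 -> 5.6%
        assert 100.0 * 1.4 / 25.0 == pytest.approx(5.6)


class TestRoiSelect:
    def test_enclosing_box_selects_all(self, sphere10):
        vmap = VertexMap(np.arange(sphere10.n_vertices, dtype=float),
                         np.ones(sphere10.n_vertices, bool), 0, "displacement")
        box = RoiBox((-20, -20, -20), (20, 20, 20))
        vals, ok = roi_select(vmap, sphere10.vertices, box)
        assert len(vals) == sphere10.n_vertices and ok.all()

    def test_disjoint_box_errors(self, sphere10):
        vmap = VertexMap(np.zeros(sphere10.n_vertices),
                         np.ones(sphere10.n_vertices, bool), 0, "displacement")
        with pytest.raises(EmptyRoiError):
            roi_select(vmap, sphere10.vertices, RoiBox((100, 100, 100), (110, 110, 110)))

    def test_static_box_keeps_reference_membership(self, sphere10):
        # reference-indexed maps use reference positions: a vertex that moved
        # out of the box at systole still counts at every phase
        box = RoiBox((-20, -20, -20), (20, 20, 20))
        moved_out = sphere10.vertices + (100.0, 0.0, 0.0)
        state = make_state(sphere10, moved_out)
        vmap = displacement_map(sphere10, state, 1)
        vals, ok = roi_select(vmap, sphere10.vertices, box)  # reference positions
        assert len(vals) == sphere10.n_vertices
        assert np.allclose(vals, 100.0)


class TestPhaseCurves:
    def _toy_maps(self, disp_values):
        n = len(disp_values)
        ones = np.ones(n, bool)
        pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
        maps = {
            "disp": VertexMap(np.asarray(disp_values, float), ones, 0, "displacement"),
            "diam": VertexMap(np.full(n, 20.0), ones, 0, "diameter"),
            "chg": VertexMap(np.zeros(n), ones, 0, "diameter_change"),
            "pct": VertexMap(np.zeros(n), ones, 0, "diameter_change_pct"),
        }
        return maps, pos

    def test_hand_arithmetic(self):
        maps, pos = self._toy_maps([1.0, 2.0, 6.0])
        box = RoiBox((-1, -1, -1), (10, 1, 1))
        curves = phase_curves([maps["disp"]], [maps["diam"]], [maps["chg"]],
                              [maps["pct"]], pos, [pos], box)
        row = curves.table.iloc[0]
        assert row.mean_displacement_mm == pytest.approx(3.0)
        assert row.max_displacement_mm == pytest.approx(6.0)
        assert row.mean_diameter_mm == pytest.approx(20.0)

    def test_invalid_values_excluded(self):
        maps, pos = self._toy_maps([1.0, 2.0, 6.0])
        maps["disp"].valid[2] = False
        box = RoiBox((-1, -1, -1), (10, 1, 1))
        curves = phase_curves([maps["disp"]], [maps["diam"]], [maps["chg"]],
                              [maps["pct"]], pos, [pos], box)
        assert curves.table.iloc[0].mean_displacement_mm == pytest.approx(1.5)
        assert curves.table.iloc[0].max_displacement_mm == pytest.approx(2.0)

    def test_csv_round_trip(self, tmp_path):
        from aortamotion.motion import MotionCurves

        maps, pos = self._toy_maps([1.0, 2.0, 6.0])
        box = RoiBox((-1, -1, -1), (10, 1, 1))
        curves = phase_curves([maps["disp"]], [maps["diam"]], [maps["chg"]],
                              [maps["pct"]], pos, [pos], box)
        curves.to_csv(tmp_path / "c.csv")
        back = MotionCurves.from_csv(tmp_path / "c.csv")
        assert back.n_phases == 1
        assert back.metric("mean_displacement_mm")[0] == pytest.approx(3.0)


class TestVertexMap:
    def test_rejects_nonfinite_valid_values(self):
        with pytest.raises(ValueError):
            VertexMap(np.array([np.nan]), np.array([True]), 0, "displacement")

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            VertexMap(np.zeros(3), np.ones(3, bool), 0, "bogus")
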