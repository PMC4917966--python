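import math

import numpy as np
import pytest

from msclsim.geometry import (
    DegenerateGeometryError,
    HelixSegment,
    IdealizedParams,
    build_from_structure,
    build_idealized,
    closest_approach,
    crossing_angle,
    fit_helix_axis,
    interhelix_angle,
    measure_model,
    rotate_z,
    write_ca_pdb,
)


def _segment(point, direction, length=30.0, name="TM1", subunit=0):
    d = np.asarray(direction, dtype=float)
    return HelixSegment(subunit, name, (1, 20), np.asarray(point, float),
                        d / np.linalg.norm(d), length)


def ideal_helix(n_res=20, rise=1.5, twist_deg=100.0, radius=2.3, axis=None):
    """Analytic alpha-helix C-alpha coordinates along a given axis."""
    t = np.arange(n_res)
    local = np.column_stack([
        radius * np.cos(np.radians(twist_deg) * t),
        radius * np.sin(np.radians(twist_deg) * t),
        rise * t,
    ])
    if axis is None:
        return local
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    R = np.column_stack([e1, e2, axis])
    return local @ R.T


class TestFitHelixAxis:
    def test_points_on_z_axis(self):
        pts = np.column_stack([np.zeros(10), np.zeros(10), 1.5 * np.arange(10)])
        start, d, length = fit_helix_axis(pts)
        assert np.allclose(np.abs(d), [0, 0, 1])
        assert d[2] > 0  # oriented N->C
        assert length == pytest.approx(13.5)

    def test_recovers_generating_axis_of_ideal_helix(self):
        axis = np.array([0.3, -0.2, 0.93])
        axis /= np.linalg.norm(axis)
        pts = ideal_helix(20, axis=axis)
        _, d, length = fit_helix_axis(pts)
        ang = math.degrees(math.acos(abs(float(np.clip(d @ axis, -1, 1)))))
        assert ang < 0.5
        assert length == pytest.approx(28.5, abs=0.5)

    @pytest.mark.parametrize("bad", [np.zeros((3, 3)), np.ones((6, 3))])
    def test_degenerate_inputs_raise(self, bad):
        with pytest.raises(DegenerateGeometryError):
            fit_helix_axis(bad)

    def test_rigid_transform_equivariance(self, rng):
        pts = ideal_helix(15)
        R = rotate_z(37.0)
        t = rng.normal(size=3)
        _, d0, l0 = fit_helix_axis(pts)
        _, d1, l1 = fit_helix_axis(pts @ R.T + t)
        assert np.allclose(R @ d0, d1, atol=1e-6)
        assert l0 == pytest.approx(l1, abs=1e-9)


class TestAngles:
    def test_parallel_crossing_angle_is_zero(self):
        a = _segment([0, 0, 0], [0, 0, 1])
        b = _segment([8, 0, 0], [0, 0, 1])
        assert crossing_angle(a, b) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("phi", [35.0, -35.0, 60.0])
    def test_constructed_rotation_about_connector(self, phi):
        # b is a's axis rotated by phi (right-handed) about the +x connector
        a = _segment([0, 0, -15], [0, 0, 1])
        c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))
        b = _segment([10, 0, -15 * c], [0, -s, c])
        assert crossing_angle(a, b) == pytest.approx(phi, abs=1e-6)
        assert crossing_angle(b, a) == pytest.approx(crossing_angle(a, b), abs=1e-9)

    def test_interhelix_angle_conventions(self):
        a = _segment([0, 0, 0], [0, 0, 1])
        assert interhelix_angle(a, _segment([5, 0, 0], [1, 0, 0])) == pytest.approx(90.0)
        d147 = [math.sin(math.radians(147)), 0, math.cos(math.radians(147))]
        assert interhelix_angle(a, _segment([5, 0, 0], d147)) == pytest.approx(147.0)

    def test_crossing_and_interhelix_agree_in_folded_magnitude(self):
        a = _segment([0, 0, 0], [0.2, 0.1, 0.97])
        b = _segment([9, 2, -4], [-0.3, 0.4, -0.86])
        gamma = interhelix_angle(a, b)
        folded = gamma if gamma <= 90 else 180 - gamma
        assert abs(crossing_angle(a, b)) == pytest.approx(folded, abs=1e-9)


class TestClosestApproach:
    def test_parallel_offset(self):
        a = _segment([0, 0, 0], [0, 0, 1])
        b = _segment([7, 0, 0], [0, 0, 1])
        assert closest_approach(a, b) == pytest.approx(7.0)

    def test_skew_segments_with_known_common_perpendicular(self):
        a = _segment([0, 0, 0], [1, 0, 0], length=20)
        b = _segment([10, -10, 12], [0, 1, 0], length=20)  # gap 12 along z
        assert closest_approach(a, b) == pytest.approx(12.0)

    def test_finite_segments_not_infinite_lines(self):
        a = _segment([0, 0, 0], [1, 0, 0], length=5)
        b = _segment([20, 3, 0], [1, 0, 0], length=5)
        assert closest_approach(a, b) == pytest.approx(math.hypot(15, 3))


class TestIdealizedBuild:
    def test_round_trips_requested_geometry(self, wt_model):
        meas = measure_model(wt_model)
        p = IdealizedParams()
        assert meas["cross_tm1_tm1_adj"] == pytest.approx(p.cross_tm1_tm1_adj, abs=0.5)
        assert meas["angle_tm1_tm2_same"] == pytest.approx(p.angle_tm1_tm2_same, abs=0.5)
        assert meas["angle_tm1_tm2_adj"] == pytest.approx(p.angle_tm1_tm2_adj, abs=0.5)
        assert meas["gap_tm2_tm2_adj"] == pytest.approx(p.gap_tm2_tm2_adj, abs=0.5)
        assert meas["angle_nterm_tm1"] == pytest.approx(p.angle_nterm_tm1, abs=0.5)
        # adjacent TM1/TM2 packing angle is positive, TM1/TM1 negative
        assert meas["cross_tm1_tm2_adj"] > 0
        assert meas["cross_tm1_tm1_adj"] < 0

    def test_exact_c5_symmetry(self, wt_model):
        R = rotate_z(72.0)
        for h in wt_model.helices:
            image = h.transformed(R, np.zeros(3))
            partner = wt_model.get((h.subunit_index + 1) % 5, h.name)
            assert np.allclose(image.start, partner.start, atol=1e-6)
            assert np.allclose(image.end, partner.end, atol=1e-6)

    def test_deletion_variant_has_no_nterm(self, dn_model):
        assert len(dn_model.helices) == 10
        assert not dn_model.hinges
        assert not any(h.name == "NTERM" for h in dn_model.helices)

    def test_infeasible_parameters_raise(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_idealized(IdealizedParams(cross_tm1_tm1_adj=-89.0))


class TestStructureRoundTrip:
    def test_pdb_round_trip_reproduces_model(self, wt_model, tmp_path):
        path = write_ca_pdb(wt_model, tmp_path / "fixture.pdb")
        rebuilt = build_from_structure(path)
        m0, m1 = measure_model(wt_model), measure_model(rebuilt)
        for key in m0:
            assert m1[key] == pytest.approx(m0[key], abs=0.1), key
        for h0 in wt_model.helices:
            h1 = rebuilt.get(h0.subunit_index, h0.name)
            assert np.allclose(h0.start, h1.start, atol=1e-3)

    def test_truncated_file_reports_missing_residues(self, wt_model, tmp_path):
        path = write_ca_pdb(wt_model, tmp_path / "fixture.pdb")
        lines = path.read_text().splitlines()
        kept = [l for l in lines if not (l.startswith("ATOM") and " 20 " in l and l[21] == "B")]
        trunc = tmp_path / "trunc.pdb"
        trunc.write_text("\n".join(kept) + "\n")
        with pytest.raises(ValueError, match="chain B.*\\[20\\]"):
            build_from_structure(trunc)
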