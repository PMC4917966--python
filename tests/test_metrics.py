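import math
from dataclasses import replace

import numpy as np
import pytest

from msclsim.geometry import rotate_z
from msclsim.metrics import (
    Trajectory,
    build_variant_model,
    continuity_angle,
    effective_pore_radius,
    gating_report,
    radial_displacement,
    run_variant_experiment,
    tilt_to_axis,
)
from msclsim.solver import SolverConfig, assemble_system, solve_quasistatic


@pytest.fixture(scope="module")
def rest_state(wt_model):
    system = assemble_system(wt_model, SolverConfig(sigma_max=0.0, n_increments=1))
    traj = solve_quasistatic(system)
    return system, traj


class TestTilt:
    def test_rest_tilt_matches_build_geometry(self, rest_state, wt_model):
        system, traj = rest_state
        tilt, sd = tilt_to_axis(system, traj.final, "TM1")
        d = wt_model.get(0, "TM1").axis_direction
        expected = math.degrees(math.acos(abs(float(d[2]))))
        assert tilt == pytest.approx(expected, abs=0.05)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_constructed_rotation_shifts_tilt(self, rest_state):
        system, traj = rest_state
        state = traj.final
        tilt0, _ = tilt_to_axis(system, state, "TM2")
        # rotate every TM2 by 12 deg in its own (axis, z) plane: the tilt to
        # the fivefold axis changes by exactly the rotation angle
        X = state.positions.copy()
        for (su, name), sl in system.helix_slices.items():
            if name != "TM2":
                continue
            pts = X[sl]
            c = pts.mean(axis=0)
            d = pts[-1] - pts[0]
            d /= np.linalg.norm(d)
            axis = np.cross(d, [0.0, 0.0, 1.0])
            axis /= np.linalg.norm(axis)
            K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            ang = math.radians(12.0)
            R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
            X[sl] = (pts - c) @ R.T + c
        rotated = replace(state, positions=X)
        tilt1, _ = tilt_to_axis(system, rotated, "TM2")
        assert abs(tilt1 - tilt0) == pytest.approx(12.0, abs=0.8)

    def test_unconverged_state_rejected(self, rest_state):
        system, traj = rest_state
        with pytest.raises(ValueError):
            tilt_to_axis(system, replace(traj.final, converged=False))


class TestPoreRadius:
    def test_rest_pore_from_build_parameters(self, rest_state):
        # closed TM1 N-end sits at 7 A from the axis; rod radius 2.5 A
        system, traj = rest_state
        assert effective_pore_radius(system, traj.final) == pytest.approx(4.5, abs=0.1)

    def test_matches_brute_force_scan(self, wt_run):
        system, traj, _ = wt_run
        state = traj.final
        fast = effective_pore_radius(system, state)
        # brute-force oracle: very dense resampling of every TM1 polyline
        half = 0.5 * system.mech.rest_thickness * (1 - state.thinning_pct / 100)
        best = np.inf
        for (su, name), sl in system.helix_slices.items():
            if name != "TM1":
                continue
            pts = state.positions[sl]
            t = np.linspace(0, 1, 20000)[:, None]
            for a, b in zip(pts[:-1], pts[1:]):
                dense = a + t * (b - a)
                inside = np.abs(dense[:, 2]) <= half
                if inside.any():
                    best = min(best, np.linalg.norm(dense[inside, :2], axis=1).min())
        assert fast == pytest.approx(best - 2.5, abs=0.05)

    def test_invariant_under_global_rotation(self, wt_run):
        system, traj, _ = wt_run
        state = traj.final
        rotated = replace(state, positions=state.positions @ rotate_z(29.0).T)
        assert effective_pore_radius(system, rotated) == pytest.approx(
            effective_pore_radius(system, state), abs=1e-9
        )


class TestRadialDisplacement:
    def test_identical_states_give_zero(self, rest_state):
        system, traj = rest_state
        two = Trajectory([traj.final, replace(traj.final, sigma_star=0.1)])
        mean, sd = radial_displacement(system, two, "NTERM")
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_injected_radial_translation_recovered(self, rest_state):
        system, traj = rest_state
        X = traj.final.positions.copy()
        for (su, name), sl in system.helix_slices.items():
            if name != "NTERM":
                continue
            u = X[sl, :2].mean(axis=0)
            u /= np.linalg.norm(u)
            X[sl, :2] += 6.0 * u  # rigid translation along the midpoint radius
        moved = replace(traj.final, positions=X, sigma_star=0.2)
        mean, sd = radial_displacement(system, Trajectory([traj.final, moved]), "NTERM")
        assert mean == pytest.approx(6.0, abs=0.05)

    def test_short_trajectory_rejected(self, rest_state):
        system, traj = rest_state
        with pytest.raises(ValueError):
            radial_displacement(system, Trajectory([traj.final]), "NTERM")


class TestContinuity:
    def test_rest_angle_is_the_build_link_angle(self, rest_state):
        system, traj = rest_state
        assert continuity_angle(system, traj.final, 0) == pytest.approx(95.0, abs=0.5)

    def test_collinear_axes_read_180(self, rest_state):
        system, traj = rest_state
        X = traj.final.positions.copy()
        nt, tm1 = system.helix_slices[(0, "NTERM")], system.helix_slices[(0, "TM1")]
        d = np.array([0.0, 0.0, 1.0])
        # one straight structural line: the N->C direction reverses at the
        # junction, so the two rod axes are collinear and read 180 deg
        X[tm1] = np.array([5.0, 0, 0]) + np.arange(8)[:, None] * 6.0 * d
        X[nt] = np.array([5.0, 0, -2.0]) - np.arange(8)[:, None] * 2.5 * d
        fake = replace(traj.final, positions=X)
        assert continuity_angle(system, fake, 0) == pytest.approx(180.0, abs=0.5)

    def test_opening_aligns_nterm_with_tm1(self, wt_run):
        _, _, report = wt_run
        angles = report.table.continuity_angle_deg
        assert angles.iloc[-1] > angles.iloc[0] + 20


class TestVariantExperiments:
    def test_wt_against_itself_is_identical(self, quick_config):
        a, b = run_variant_experiment("WT", 0.3, quick_config)
        assert np.allclose(a.table.values, b.table.values)

    def test_deletion_opens_less_than_wt(self, quick_config):
        dn, wt = run_variant_experiment("DELTA_NTERM", 0.3, quick_config)
        assert dn.final.pore_diameter_A < wt.final.pore_diameter_A

    def test_pore_ordering_across_variants(self, quick_config):
        pores = {}
        for v in ("WT", "+2G", "+5G", "DELTA_NTERM"):
            model = build_variant_model(v)
            system = assemble_system(model, quick_config)
            traj = solve_quasistatic(system)
            pores[v] = effective_pore_radius(system, traj.final)
        assert pores["DELTA_NTERM"] <= pores["+5G"] + 1e-3
        assert pores["+5G"] <= pores["+2G"] + 1e-3
        assert pores["+2G"] < pores["WT"]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_variant_model("+9G")


class TestReport:
    def test_report_schema_and_consistency(self, wt_run):
        _, _, report = wt_run
        t = report.table
        assert np.allclose(t.pore_diameter_A, 2 * t.pore_radius_A)
        assert t.sigma_star.is_monotonic_increasing
        for col in ("tm1_tilt_deg", "tm2_tilt_deg", "continuity_angle_deg"):
            assert ((t[col] >= 0) & (t[col] <= 180)).all()
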