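import numpy as np
import pytest
from dataclasses import replace

from msclsim.geometry import HELIX_RISE, build_idealized, rotate_z
from msclsim.metrics import build_variant_model
from msclsim.solver import (
    MechanicsParams,
    RodElement,
    SolverConfig,
    Trajectory,
    assemble_system,
    axial_bar_force,
    cantilever_tip_deflection,
    mesh_sensitivity,
    solve_quasistatic,
    von_mises_map,
)


class TestBeamBenchmarks:
    def test_cantilever_matches_euler_bernoulli_within_one_percent(self):
        tip, closed = cantilever_tip_deflection(n_elements=10)
        assert tip == pytest.approx(closed, rel=0.01)

    def test_cantilever_converges_under_refinement(self):
        errs = [
            abs(t - c) / c for t, c in (cantilever_tip_deflection(n) for n in (5, 10, 20))
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_axial_bar_closed_form(self):
        computed, closed = axial_bar_force(0.5, length=30.0)
        assert computed == pytest.approx(closed, abs=1e-12)

    def test_rod_element_validation(self):
        with pytest.raises(ValueError):
            RodElement(0, 1, rest_length=-1.0)
        with pytest.raises(ValueError):
            RodElement(0, 1, rest_length=5.0, axial_stiffness=0.0)


class TestAssembly:
    def test_wt_counts(self, wt_model):
        system = assemble_system(wt_model, SolverConfig(nodes_per_helix=8))
        assert system.n_nodes == 15 * 8
        assert len(system.segments) == 15 * 7
        assert len(system.quads) == 5  # one hinge per subunit
        assert len(system.pins) == 5
        assert len(system.loop_pairs) == 5

    def test_deletion_counts(self, dn_model):
        system = assemble_system(dn_model, SolverConfig(nodes_per_helix=8))
        assert system.n_nodes == 10 * 8
        assert len(system.pins) == 0
        assert len(system.quads) == 0

    def test_linker_extension_becomes_tether_of_n_times_rise(self):
        model = build_variant_model("+5G")
        system = assemble_system(model, SolverConfig())
        assert len(system.tethers) == 5
        assert np.allclose(system.tether_rest, 5 * HELIX_RISE)
        assert len(system.pins) == 0

    def test_gradient_matches_finite_differences(self, wt_model, rng):
        system = assemble_system(wt_model, SolverConfig())
        x0 = system.X0.ravel() + 0.03 * rng.standard_normal(system.n_nodes * 3)
        _, G = system.energy_grad(x0, 0.25)
        eps = 1e-6
        for k in rng.choice(x0.size, size=6, replace=False):
            xp, xm = x0.copy(), x0.copy()
            xp[k] += eps
            xm[k] -= eps
            Ep, _ = system.energy_grad(xp, 0.25)
            Em, _ = system.energy_grad(xm, 0.25)
            assert G[k] == pytest.approx((Ep - Em) / (2 * eps), rel=1e-4, abs=1e-8)


class TestQuasistatic:
    def test_zero_load_is_identity(self, wt_model):
        system = assemble_system(wt_model, SolverConfig(sigma_max=0.0, n_increments=1))
        traj = solve_quasistatic(system)
        assert traj.completed
        assert np.allclose(traj.final.positions, system.X0, atol=1e-4)
        assert np.allclose(traj.final.element_stress, 0.0, atol=1e-5)

    def test_determinism(self, wt_model, quick_config):
        runs = []
        for _ in range(2):
            system = assemble_system(wt_model, quick_config)
            runs.append(solve_quasistatic(system).final.positions)
        assert np.array_equal(runs[0], runs[1])

    def test_c5_equivariance_of_the_solution(self, wt_model, quick_config):
        system = assemble_system(wt_model, quick_config)
        state = solve_quasistatic(system).final
        R = rotate_z(72.0)
        for (su, name), sl in system.helix_slices.items():
            rotated = state.positions[sl] @ R.T
            partner = state.positions[system.helix_slices[((su + 1) % 5, name)]]
            assert np.allclose(rotated, partner, atol=1e-4)

    def test_nondimensional_invariance_to_the_modulus(self, wt_model, quick_config):
        out = []
        # power-of-two factor: scaling E and A_H by 2**k keeps every
        # nondimensional constant bit-identical in IEEE arithmetic
        for scale in (1.0, 4.0):
            mech = MechanicsParams(
                young_modulus_gpa=0.2 * scale,
                vdw=replace(MechanicsParams().vdw, hamaker_zj=21.0 * scale),
            )
            system = assemble_system(wt_model, quick_config, mech)
            out.append(solve_quasistatic(system).final.positions)
        assert np.allclose(out[0], out[1], atol=1e-10)

    def test_monotone_pore_opening(self, wt_run):
        _, _, report = wt_run
        assert np.all(np.diff(report.table.pore_radius_A) > -1e-6)

    def test_nonconvergence_yields_truncated_trajectory(self, wt_model):
        cfg = SolverConfig(sigma_max=0.6, n_increments=3, tolerance=1e-16,
                           max_iterations=3, max_halvings=1)
        system = assemble_system(wt_model, cfg)
        traj = solve_quasistatic(system)
        assert not traj.completed
        assert "stability" in traj.diagnostic

    def test_trajectory_requires_increasing_sigma(self, wt_run):
        _, traj, _ = wt_run
        with pytest.raises(ValueError):
            Trajectory([traj.states[1], traj.states[0]])


class TestStressMap:
    def test_unloaded_state_is_stress_free(self, wt_model):
        system = assemble_system(wt_model, SolverConfig(sigma_max=0.0, n_increments=1))
        state = solve_quasistatic(system).final
        stress = von_mises_map(system, state)
        for vals in stress.values():
            assert np.allclose(vals, 0.0, atol=1e-5)

    def test_pure_axial_stress_is_force_over_area(self, wt_model):
        from msclsim.solver import ROD_AREA, _element_von_mises

        system = assemble_system(wt_model, SolverConfig())
        X = system.X0.copy()
        sl = system.helix_slices[(0, "TM1")]
        seg = X[sl.start + 1] - X[sl.start]
        # uniform 1% stretch of one helix about its first node
        X[sl] = X[sl.start] + (X[sl] - X[sl.start]) * 1.01
        stress = _element_von_mises(system, X)
        k = next(i for i, (a, b) in enumerate(system.segments) if a == sl.start)
        expected = system.seg_ka[k] * 0.01 * np.linalg.norm(seg) / ROD_AREA
        assert stress[k] == pytest.approx(expected, rel=1e-9)

    def test_unconverged_state_rejected(self, wt_run):
        system, traj, _ = wt_run
        bad = replace_converged(traj.final)
        with pytest.raises(ValueError):
            von_mises_map(system, bad)


def replace_converged(state):
    from dataclasses import replace as drep

    return drep(state, converged=False)


class TestMeshSensitivity:
    def test_refinement_report(self, wt_model):
        cfg = SolverConfig(sigma_max=0.3, n_increments=6)
        out = mesh_sensitivity(wt_model, cfg, levels=(4, 8, 16))
        assert [row["nodes_per_helix"] for row in out["levels"]] == [4, 8, 16]
        assert out["converged_at_nodes_per_helix"] in (4, 8)
        # self-convergence: tilt and pore change < 2% from 8 to 16 nodes
        r8, r16 = out["levels"][1], out["levels"][2]
        assert abs(r16["tm1_tilt_deg"] - r8["tm1_tilt_deg"]) / r8["tm1_tilt_deg"] < 0.02
        assert abs(r16["pore_radius_A"] - r8["pore_radius_A"]) / r8["pore_radius_A"] < 0.02

    def test_too_few_levels_rejected(self, wt_model):
        with pytest.raises(ValueError):
            mesh_sensitivity(wt_model, levels=(4, 8))
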