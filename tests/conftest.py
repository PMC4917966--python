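import numpy as np
import pytest

from msclsim.geometry import build_idealized
from msclsim.metrics import gating_report
from msclsim.solver import SolverConfig, assemble_system, solve_quasistatic


@pytest.fixture(scope="session")
def wt_model():
    return build_idealized()


@pytest.fixture(scope="session")
def dn_model():
    return build_idealized(has_nterm=False)


@pytest.fixture(scope="session")
def wt_run(wt_model):
    """Full WT opening ramp to sigma* = 0.6 with the frozen defaults."""
    system = assemble_system(wt_model, SolverConfig())
    traj = solve_quasistatic(system)
    return system, traj, gating_report(system, traj, "WT")


@pytest.fixture(scope="session")
def dn_run(dn_model):
    """N-terminus-deleted ramp under the identical load program."""
    system = assemble_system(dn_model, SolverConfig())
    traj = solve_quasistatic(system)
    return system, traj, gating_report(system, traj, "DELTA_NTERM")


@pytest.fixture(scope="session")
def quick_config():
    """Short ramp for structural/property tests that do not need full opening."""
    return SolverConfig(sigma_max=0.3, n_increments=6)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
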