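"""Gating observables from solved states and variant comparison experiments.

All helix-level metrics refit a straight axis to the deformed nodes of each
helix (the rods bend slightly), then reduce over the five subunits with a
standard deviation.  Angles are measured against the central fivefold axis
(+z); the effective pore is backbone-based: centerline distance to the axis
minus the 2.5 A rod radius, minimized over depth slices through the
membrane span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ChannelModel, IdealizedParams, build_idealized, fit_helix_axis
from .solver import (
    AssembledSystem,
    MechanicsParams,
    SolverConfig,
    SystemState,
    Trajectory,
    assemble_system,
    solve_quasistatic,
    von_mises_map,
)

__all__ = [
    "GatingReport",
    "VARIANTS",
    "tilt_to_axis",
    "effective_pore_radius",
    "radial_displacement",
    "continuity_angle",
    "gating_report",
    "build_variant_model",
    "run_variant_experiment",
]

VARIANTS = ("WT", "DELTA_NTERM", "+2G", "+5G")

ROD_RADIUS = 2.5
PORE_Z_STEP = 0.25


def _require_converged(state: SystemState) -> None:
    if not state.converged:
        raise ValueError("metric requires a converged state")


def _helix_axes(system: AssembledSystem, state: SystemState, name: str):
    """Refit (direction, start, end, mid) per subunit for one helix class."""
    out = []
    for (su, hname), sl in system.helix_slices.items():
        if hname != name:
            continue
        pts = state.positions[sl]
        start, d, length = fit_helix_axis(pts)
        out.append((su, d, start, start + length * d, pts.mean(axis=0)))
    if not out:
        raise ValueError(f"model has no {name} segments")
    return sorted(out, key=lambda t: t[0])


def tilt_to_axis(
    system: AssembledSystem, state: SystemState, helix: str = "TM1"
) -> tuple[float, float]:
    """Mean (+/- s.d.) angle between a helix class axis and the fivefold axis.

    The fold to [0, 90] treats the axis as a line: a helix lying in the
    membrane plane reads 90 deg, one along the pore axis 0 deg.
    """
    _require_converged(state)
    tilts = []
    for _, d, *_ in _helix_axes(system, state, helix):
        tilts.append(math.degrees(math.acos(min(1.0, abs(float(d[2]))))))
    return float(np.mean(tilts)), float(np.std(tilts))


def effective_pore_radius(
    system: AssembledSystem,
    state: SystemState,
    z_step: float = PORE_Z_STEP,
) -> float:
    """Backbone effective pore radius (A), clamped at zero.

    Minimum over depth slices through the (thinned) membrane span of the
    distance from the fivefold axis to the nearest TM1 centerline, minus the
    rod radius.  The rod centerlines are the deformed node polylines,
    resampled at sub-Angstrom resolution.
    """
    _require_converged(state)
    half = 0.5 * system.mech.rest_thickness * (1.0 - state.thinning_pct / 100.0)
    best = np.inf
    found = False
    for (su, hname), sl in system.helix_slices.items():
        if hname != "TM1":
            continue
        found = True
        pts = state.positions[sl]
        # resample the polyline densely (finer than the z scan)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(seg)])
        n_dense = max(int(t[-1] / (z_step / 2.0)), 2)
        td = np.linspace(0.0, t[-1], n_dense)
        dense = np.column_stack([np.interp(td, t, pts[:, k]) for k in range(3)])
        inside = np.abs(dense[:, 2]) <= half
        if not np.any(inside):
            continue
        r = np.linalg.norm(dense[inside, :2], axis=1)
        best = min(best, float(r.min()))
    if not found:
        raise ValueError("model has no TM1 segments")
    if not np.isfinite(best):
        return 0.0
    return max(best - ROD_RADIUS, 0.0)


def radial_displacement(
    system: AssembledSystem, traj: Trajectory, helix: str = "NTERM"
) -> tuple[float, float]:
    """Change in helix-midpoint cylindrical radius, first vs last state.

    Averaged over the five subunits with s.d.; positive = outward movement.
    """
    if len(traj) < 2:
        raise ValueError("radial displacement needs a trajectory with >= 2 states")
    first = {su: mid for su, *_, mid in _helix_axes(system, traj.states[0], helix)}
    last = {su: mid for su, *_, mid in _helix_axes(system, traj.final, helix)}
    deltas = [
        float(np.linalg.norm(last[su][:2]) - np.linalg.norm(first[su][:2]))
        for su in first
    ]
    return float(np.mean(deltas)), float(np.std(deltas))


def continuity_angle(system: AssembledSystem, state: SystemState, subunit: int = 0) -> float:
    """N-term/TM1 inter-axis angle (deg); approaches 180 as the two helices
    align into a contiguous helix during opening."""
    _require_converged(state)
    nt = {su: d for su, d, *_ in _helix_axes(system, state, "NTERM")}
    tm = {su: d for su, d, *_ in _helix_axes(system, state, "TM1")}
    if subunit not in nt:
        raise ValueError(f"no NTERM in subunit {subunit}")
    c = float(np.clip(nt[subunit] @ tm[subunit], -1.0, 1.0))
    return math.degrees(math.acos(c))


@dataclass
class GatingReport:
    """Per-increment gating observables for one run."""

    variant: str
    table: pd.DataFrame
    completed: bool
    diagnostic: str = ""

    @property
    def final(self) -> pd.Series:
        return self.table.iloc[-1]


def gating_report(system: AssembledSystem, traj: Trajectory, variant: str = "WT") -> GatingReport:
    """Assemble the standard observable table from a trajectory."""
    rows = []
    has_nterm = system.model.has_nterm
    first = traj.states[0]
    tilt1_0, _ = tilt_to_axis(system, first, "TM1")
    tilt2_0, _ = tilt_to_axis(system, first, "TM2")
    for state in traj.states:
        tilt1, sd1 = tilt_to_axis(system, state, "TM1")
        tilt2, sd2 = tilt_to_axis(system, state, "TM2")
        pore_r = effective_pore_radius(system, state)
        row = {
            "sigma_star": state.sigma_star,
            "tm1_tilt_deg": tilt1,
            "tm1_tilt_sd": sd1,
            "tm1_tilt_change_deg": tilt1 - tilt1_0,
            "tm2_tilt_deg": tilt2,
            "tm2_tilt_change_deg": tilt2 - tilt2_0,
            "pore_radius_A": pore_r,
            "pore_diameter_A": 2.0 * pore_r,
            "thinning_pct": state.thinning_pct,
        }
        stress = von_mises_map(system, state)
        for cls, vals in stress.items():
            row[f"vm_max_{cls.lower()}"] = float(vals.max())
            row[f"vm_mean_{cls.lower()}"] = float(vals.mean())
        if has_nterm:
            row["continuity_angle_deg"] = continuity_angle(system, state, 0)
            sub = Trajectory([traj.states[0], state]) if state is not first else None
            if sub is not None:
                dr, dr_sd = radial_displacement(system, sub, "NTERM")
            else:
                dr, dr_sd = 0.0, 0.0
            row["nterm_radial_disp_A"] = dr
            row["nterm_radial_disp_sd"] = dr_sd
        rows.append(row)
    return GatingReport(variant, pd.DataFrame(rows), traj.completed, traj.diagnostic)


def build_variant_model(
    variant: str, params: IdealizedParams | None = None
) -> ChannelModel:
    """Idealized closed-state model for WT, the N-term deletion, or +nG linkers."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if variant == "DELTA_NTERM":
        return build_idealized(params, has_nterm=False)
    model = build_idealized(params, has_nterm=True)
    if variant == "WT":
        return model
    n_ext = {"+2G": 2, "+5G": 5}[variant]
    hinges = [replace(h, linker_extension_residues=n_ext) for h in model.hinges]
    return ChannelModel(model.helices, hinges, model.loops, has_nterm=True)


def run_variant_experiment(
    variant: str,
    sigma_max: float = 0.6,
    config: SolverConfig | None = None,
    mech: MechanicsParams | None = None,
    params: IdealizedParams | None = None,
) -> tuple[GatingReport, GatingReport]:
    """Run a variant and the WT reference under the same load program.

    Returns ``(variant_report, wt_report)``.  The deletion variant is
    expected to open less at matched load; linker extensions to need more
    load for the same pore radius.
    """
    cfg = config or SolverConfig()
    cfg = replace(cfg, sigma_max=sigma_max)
    reports = []
    for v in (variant, "WT"):
        model = build_variant_model(v, params)
        system = assemble_system(model, cfg, mech)
        traj = solve_quasistatic(system)
        reports.append(gating_report(system, traj, v))
    return reports[0], reports[1]
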