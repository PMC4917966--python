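"""Quasi-static nonlinear solver for the rod/hinge/spring channel model.

Each helix is discretized as a chain of nodes carrying translational degrees
of freedom.  Rod elasticity is a discrete elastic-rod formulation: axial
springs along segments plus angular (curvature) springs at interior nodes
with Voronoi weights, which converges to Euler-Bernoulli beam theory under
refinement and handles the large rigid rotations of gating without a
rotation parametrization.  The load case is torsion-free and the G14 hinge
releases rotation, so rod joints behave as (optionally weakly stiffened)
ball joints.

Loading is incremental: for each nondimensional membrane tension sigma* the
depth-resolved pressure-profile pull and the van der Waals adhesion to the
(dilating) lipid inner surface are assembled, and the total potential energy
is minimized (L-BFGS with analytic gradient).  Convergence of an increment
means the force-residual infinity norm fell below the solver tolerance.
Everything is dimensionless: lengths in Angstrom, stresses in units of the
protein Young's modulus E, forces in E*A^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .geometry import ChannelModel, HELIX_RISE
from .membrane import BilayerPatch, build_pressure_profile, thinning_response
from .vdw import DEFAULT_YOUNG_MODULUS_GPA, VdwLaw, vdw_energy, vdw_traction

__all__ = [
    "RodElement",
    "MechanicsParams",
    "SolverConfig",
    "SystemState",
    "Trajectory",
    "AssembledSystem",
    "assemble_system",
    "solve_quasistatic",
    "von_mises_map",
    "mesh_sensitivity",
    "cantilever_tip_deflection",
    "axial_bar_force",
]

ROD_DIAMETER = 5.0
ROD_AREA = math.pi * (ROD_DIAMETER / 2.0) ** 2  # 19.63 A^2
ROD_INERTIA = math.pi * ROD_DIAMETER**4 / 64.0  # 30.68 A^4


@dataclass(frozen=True)
class RodElement:
    """One rod segment between two nodes; stiffnesses are ratios to E."""

    node_a: int
    node_b: int
    rest_length: float
    diameter: float = ROD_DIAMETER
    axial_stiffness: float = 1.0
    bending_stiffness: float = 1.0
    torsional_stiffness: float = 1.0  # unused in the torsion-free load case

    def __post_init__(self) -> None:
        if self.rest_length <= 0:
            raise ValueError("rest length must be positive")
        if min(self.axial_stiffness, self.bending_stiffness, self.torsional_stiffness) <= 0:
            raise ValueError("stiffness ratios must be positive")


@dataclass(frozen=True)
class MechanicsParams:
    """The frozen default calibration of the continuum model.

    These are the quantities the underlying experiments do not pin down
    individually (rod/loop stiffness ratios, band pressure partition, lipid
    exposure of each helix class, membrane rim compliance); they were
    calibrated once against the gating observables and are configurable.
    """

    young_modulus_gpa: float = DEFAULT_YOUNG_MODULUS_GPA
    stiffness_ratio: dict[str, float] = field(
        default_factory=lambda: {"NTERM": 1.0, "TM1": 1.0, "TM2": 1.0}
    )
    hinge_stiffness_ratio: float = 1e-4
    loop_stiffness_ratio: float = 1e-2
    # lipid exposure: fraction of a rod's side area facing lipid.  TM2 and the
    # N-term face the bilayer; pore-lining TM1 is shielded near the cytoplasmic
    # constriction but increasingly lipid-exposed toward its flared
    # periplasmic end (tm1_exposure_top), where the pore funnel widens.
    lipid_exposure: dict[str, float] = field(
        default_factory=lambda: {"NTERM": 1.5, "TM1": 0.3, "TM2": 1.0}
    )
    tm1_exposure_top: float = 0.6
    # membrane
    rest_thickness: float = 33.3
    head_width: float = 5.0
    interface_width: float = 4.0
    head_tension_fraction: float = 1.0
    areal_modulus: float = 3.4  # sets 15% thinning at sigma* = 0.6
    # lipid hole rim moves outward by rim_compliance * sigma* * rim_reference,
    # modulated along depth by (1 + rim_taper * z/h0): a positive taper opens
    # the periplasmic mouth into the funnel shape of the expanded channel
    rim_compliance: float = 1.35
    rim_reference_radius: float = 25.0
    rim_taper: float = 1.25
    # progressive yield: the rim advance grows as sigma*(1 + rim_accel*sigma)
    rim_accel: float = -0.35
    # adhesion law
    vdw: VdwLaw = field(default_factory=lambda: VdwLaw(hamaker_zj=21.0, d0=3.0))
    # the lipid rim yields under protein indentation: the repulsive branch is
    # linearized once it reaches repulsion_cap times the peak attraction
    repulsion_cap: float = 2.0
    # the tension pull on a node fades once it outruns its local rim anchor
    # by more than drag_slack (A), over a decay length drag_decay (A): the
    # membrane can only pull at the protein-lipid boundary, not drag a helix
    # arbitrarily deep into the annulus
    drag_slack: float = 5.0
    drag_decay: float = 0.6
    # hydrophobic matching: lipid-exposed nodes are tethered in depth to
    # their rest membrane station, which compresses as the bilayer thins
    # (z_target = z0 * h/h0); stiffness per unit exposed area, E/A^3
    z_confinement: float = 0.03
    # the interfacial N-term adheres laterally to the spreading lower leaflet:
    # each node is tethered radially to an anchor advancing as
    # nterm_advance_max * (1 - exp(-sigma*/nterm_advance_sigma)) — the
    # leaflet's lateral redistribution saturates — with stiffness
    # nterm_anchor per unit area.  The spring sustains the transmitted force
    # at equilibrium, unlike a dead load, so the N-term carries its drag as
    # axial tension in the open state
    nterm_advance_max: float = 11.2
    nterm_advance_sigma: float = 0.18
    nterm_anchor: float = 0.1


@dataclass(frozen=True)
class SolverConfig:
    """Continuation schedule and convergence controls."""

    sigma_max: float = 0.6
    n_increments: int = 30
    tolerance: float = 1e-5  # force-residual infinity norm, E*A^2
    max_iterations: int = 4000
    nodes_per_helix: int = 8
    max_halvings: int = 5
    seed: int = 0  # unused: the solver is deterministic

    def __post_init__(self) -> None:
        if self.sigma_max < 0 or self.n_increments < 1:
            raise ValueError("need sigma_max >= 0 and n_increments >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def increments(self) -> np.ndarray:
        if self.sigma_max == 0.0:
            return np.array([0.0])
        return np.linspace(0.0, self.sigma_max, self.n_increments + 1)


@dataclass
class SystemState:
    """Solved configuration at one load increment."""

    sigma_star: float
    positions: np.ndarray  # (n_nodes, 3)
    converged: bool
    residual_norm: float
    thinning_pct: float
    element_stress: np.ndarray  # per-segment von Mises, stress/E

    def __post_init__(self) -> None:
        if self.converged and np.any(self.element_stress < 0):
            raise ValueError("von Mises stresses must be non-negative")


@dataclass
class Trajectory:
    """Converged states in order of strictly increasing sigma*."""

    states: list[SystemState]
    completed: bool = True
    diagnostic: str = ""

    def __post_init__(self) -> None:
        sig = [s.sigma_star for s in self.states]
        if any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("sigma* must strictly increase along the trajectory")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final(self) -> SystemState:
        return self.states[-1]


class AssembledSystem:
    """Discretized rods, connectors and load bookkeeping for one model."""

    def __init__(self, model: ChannelModel, config: SolverConfig, mech: MechanicsParams):
        self.model = model
        self.config = config
        self.mech = mech
        self._build_nodes()
        self._build_elements()
        self._build_connectors()
        self._build_loads()

    # -- construction ------------------------------------------------------

    def _build_nodes(self) -> None:
        n_per = self.config.nodes_per_helix
        xs, helix_of, slices = [], [], {}
        for h_idx, h in enumerate(self.model.helices):
            t = np.linspace(0.0, 1.0, n_per)
            pts = h.start[None, :] + t[:, None] * (h.end - h.start)[None, :]
            slices[(h.subunit_index, h.name)] = slice(len(xs) * 0, 0)  # fixed below
            start = sum(p.shape[0] for p in xs)
            xs.append(pts)
            helix_of.extend([h_idx] * n_per)
            slices[(h.subunit_index, h.name)] = slice(start, start + n_per)
        self.X0 = np.concatenate(xs, axis=0)
        self.n_nodes = self.X0.shape[0]
        self.helix_of_node = np.asarray(helix_of)
        self.helix_slices = slices
        self.depth_tags = self.X0[:, 2].copy()
        self.free = np.ones(self.n_nodes, dtype=bool)

    def _class_of(self, h_idx: int) -> str:
        return self.model.helices[h_idx].name

    def _build_elements(self) -> None:
        segs, l0, ka, cls = [], [], [], []
        bends, cb = [], []
        node_len = np.zeros(self.n_nodes)  # Voronoi tributary length
        for (su, name), sl in self.helix_slices.items():
            idx = np.arange(sl.start, sl.stop)
            ratio = self.mech.stiffness_ratio[name]
            seg_len = float(np.linalg.norm(self.X0[idx[1]] - self.X0[idx[0]]))
            for a, b in zip(idx[:-1], idx[1:]):
                segs.append((a, b))
                l0.append(seg_len)
                ka.append(ratio * ROD_AREA / seg_len)
                cls.append(name)
            for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
                bends.append((a, b, c))
                cb.append(ratio * ROD_INERTIA / seg_len)
            node_len[idx] = seg_len
            node_len[idx[0]] = node_len[idx[-1]] = seg_len / 2.0
        self.segments = np.asarray(segs)
        self.seg_rest = np.asarray(l0)
        self.seg_ka = np.asarray(ka)
        self.seg_class = np.asarray(cls)
        self.bends = np.asarray(bends)
        self.bend_c = np.asarray(cb)
        self.node_tributary = node_len

    def _build_connectors(self) -> None:
        pins, kp = [], []
        tethers, kt, lt = [], [], []
        quads, cq, th0 = [], [], []
        loops, kl, lrest, ltab = [], [], [], []
        for hinge in self.model.hinges:
            su = hinge.subunit_index
            nt = self.helix_slices[(su, "NTERM")]
            tm1 = self.helix_slices[(su, "TM1")]
            i, j = nt.stop - 1, tm1.start
            n_ext = hinge.linker_extension_residues
            if n_ext == 0:
                pins.append((i, j))
                kp.append(ROD_AREA / HELIX_RISE)
            else:
                # +nG linker: a tension-only tether of rest length n * rise
                # with negligible bending resistance (it buckles freely)
                tethers.append((i, j))
                lt.append(n_ext * HELIX_RISE)
                kt.append(ROD_AREA / (n_ext * HELIX_RISE))
            e1 = self.X0[nt.stop - 1] - self.X0[nt.stop - 2]
            e2 = self.X0[tm1.start + 1] - self.X0[tm1.start]
            ang = _angle_between(e1, e2)
            stiff = hinge.rotational_stiffness
            c_h = (stiff if stiff > 0 else self.mech.hinge_stiffness_ratio) * (
                ROD_INERTIA / self.seg_rest[0]
            )
            if n_ext == 0:
                quads.append((nt.stop - 2, nt.stop - 1, tm1.start, tm1.start + 1))
                cq.append(c_h)
                th0.append(ang)
        for loop in self.model.loops:
            (su_a, name_a, end_a), (su_b, name_b, end_b) = loop.endpoints
            ia = self._end_node(su_a, name_a, end_a)
            ib = self._end_node(su_b, name_b, end_b)
            d0 = float(np.linalg.norm(self.X0[ia] - self.X0[ib]))
            loops.append((ia, ib))
            lrest.append(d0)
            kl.append(self.mech.loop_stiffness_ratio * ROD_AREA / max(d0, 1.0))
            ltab.append(loop.force_extension_table)
        self.pins = np.asarray(pins, dtype=int).reshape(-1, 2)
        self.pin_k = np.asarray(kp)
        self.tethers = np.asarray(tethers, dtype=int).reshape(-1, 2)
        self.tether_k = np.asarray(kt)
        self.tether_rest = np.asarray(lt)
        self.quads = np.asarray(quads, dtype=int).reshape(-1, 4)
        self.quad_c = np.asarray(cq)
        self.quad_theta0 = np.asarray(th0)
        self.loop_pairs = np.asarray(loops, dtype=int).reshape(-1, 2)
        self.loop_k = np.asarray(kl)
        self.loop_rest = np.asarray(lrest)
        self.loop_tables = ltab

    def _end_node(self, su: int, name: str, end: str) -> int:
        sl = self.helix_slices[(su, name)]
        return sl.start if end == "start" else sl.stop - 1

    def _build_loads(self) -> None:
        mech = self.mech
        d = ROD_DIAMETER
        exposure = np.array(
            [mech.lipid_exposure[self._class_of(h)] for h in self.helix_of_node]
        )
        # TM1 exposure ramps from its base value at and below the membrane
        # midplane up to tm1_exposure_top at the periplasmic end
        is_tm1 = np.array([self._class_of(h) == "TM1" for h in self.helix_of_node])
        if np.any(is_tm1):
            z = self.depth_tags[is_tm1]
            ztop = z.max()
            frac = np.clip(z / max(ztop, 1e-9), 0.0, 1.0)
            base = mech.lipid_exposure["TM1"]
            exposure[is_tm1] = base + (mech.tm1_exposure_top - base) * frac
        self.node_area = self.node_tributary * d * exposure
        # adhesion: every lipid-exposed node is anchored at its rest gap D0
        # from the local lipid inner surface; the surface dilates with sigma*
        r0 = np.linalg.norm(self.X0[:, :2], axis=1)
        self.vdw_rtag = r0 + d / 2.0 + mech.vdw.d0
        self.vdw_area = self.node_area.copy()
        self._is_nterm = np.array(
            [self._class_of(h) == "NTERM" for h in self.helix_of_node]
        )
        # the N-term rides on the bilayer lower surface, not the inner rim
        self.vdw_area[self._is_nterm] = 0.0
        self.centroid0 = self.X0.mean(axis=0)

    # -- energy and gradient ----------------------------------------------

    def _profile_delta(self, sigma_star: float) -> np.ndarray:
        """Per-node tension-driven radial pull (load relative to rest)."""
        mech = self.mech
        kw = dict(
            thickness=mech.rest_thickness,
            head_width=mech.head_width,
            interface_width=mech.interface_width,
            head_tension_fraction=mech.head_tension_fraction,
            head_rest_pressure=0.0,
            tail_rest_pressure=0.0,
        )
        prof = build_pressure_profile(sigma_star=sigma_star, **kw)
        rest = build_pressure_profile(sigma_star=0.0, **kw)
        dp = prof.pressure(self.depth_tags) - rest.pressure(self.depth_tags)
        return -dp * self.node_area  # outward-positive radial force

    def _rim_advance(self, sigma_star: float) -> np.ndarray:
        """Per-node outward advance of the local lipid rim anchor (A)."""
        mech = self.mech
        shape = 1.0 + mech.rim_taper * self.depth_tags / mech.rest_thickness
        load = sigma_star * (1.0 + mech.rim_accel * sigma_star)
        adv = mech.rim_compliance * load * mech.rim_reference_radius * shape
        adv_nterm = mech.nterm_advance_max * (
            1.0 - np.exp(-sigma_star / mech.nterm_advance_sigma)
        )
        return np.where(self._is_nterm, adv_nterm, adv)

    def _yield_gap(self) -> float:
        """Gap below which the rim yields: |S| = repulsion_cap * S_max,attr."""
        if not hasattr(self, "_yield_gap_cache"):
            from scipy.optimize import brentq

            law, Egpa = self.mech.vdw, self.mech.young_modulus_gpa
            m, n = law.exponents
            x_peak = (n / m) ** (1.0 / (n - m))  # D/D0 of peak attraction
            s_peak = vdw_traction(x_peak * law.d0, law, Egpa)
            target = -self.mech.repulsion_cap * s_peak
            self._yield_gap_cache = brentq(
                lambda d: vdw_traction(d, law, Egpa) - target, 0.05 * law.d0, law.d0
            )
        return self._yield_gap_cache

    def energy_grad(self, x: np.ndarray, sigma_star: float) -> tuple[float, np.ndarray]:
        X = x.reshape(-1, 3)
        E = 0.0
        G = np.zeros_like(X)
        mech = self.mech

        # axial springs
        ea = X[self.segments[:, 1]] - X[self.segments[:, 0]]
        ln = np.linalg.norm(ea, axis=1)
        stretch = ln - self.seg_rest
        E += 0.5 * np.sum(self.seg_ka * stretch**2)
        f = (self.seg_ka * stretch / np.maximum(ln, 1e-12))[:, None] * ea
        np.add.at(G, self.segments[:, 0], -f)
        np.add.at(G, self.segments[:, 1], f)

        # rod curvature springs (1 - cos theta)
        if len(self.bends):
            E_b, G_b = _bend_energy(X, self.bends, self.bend_c)
            E += E_b
            G += G_b

        # hinge angular springs with rest angle
        if len(self.quads):
            E_q, G_q = _quad_angle_energy(X, self.quads, self.quad_c, self.quad_theta0)
            E += E_q
            G += G_q

        # pins (two-sided) and linker tethers (tension-only)
        for pairs, ks, rests, tension_only in (
            (self.pins, self.pin_k, np.zeros(len(self.pins)), False),
            (self.tethers, self.tether_k, self.tether_rest, True),
        ):
            if not len(pairs):
                continue
            e = X[pairs[:, 1]] - X[pairs[:, 0]]
            d = np.linalg.norm(e, axis=1)
            ext = d - rests
            if tension_only:
                ext = np.maximum(ext, 0.0)
            E += 0.5 * np.sum(ks * ext**2)
            coef = ks * ext / np.maximum(d, 1e-12)
            f = coef[:, None] * e
            np.add.at(G, pairs[:, 0], -f)
            np.add.at(G, pairs[:, 1], f)

        # loop springs (linear default or tabulated nonlinear wires)
        for (ia, ib), k, rest, table in zip(
            self.loop_pairs, self.loop_k, self.loop_rest, self.loop_tables
        ):
            e = X[ib] - X[ia]
            d = float(np.linalg.norm(e))
            ext = d - rest
            if table is None:
                E += 0.5 * k * ext**2
                fmag = k * ext
            else:
                E += _table_energy(table, ext)
                fmag = _table_force(table, ext)
            f = fmag / max(d, 1e-12) * e
            G[ia] -= f
            G[ib] += f

        # membrane pressure-profile pull (radial load at tagged depth), fading
        # once a node outruns its local rim anchor by more than the slack
        fmem = self._profile_delta(sigma_star)
        fmem = np.where(self._is_nterm, 0.0, fmem)  # N-term: anchored drag below
        r = np.linalg.norm(X[:, :2], axis=1)
        r0 = np.linalg.norm(self.X0[:, :2], axis=1)
        rim_advance = self._rim_advance(sigma_star)
        pen = (r - r0) - rim_advance - mech.drag_slack
        s_pen = np.maximum(pen, 0.0)
        w = np.exp(-s_pen / mech.drag_decay)
        # potential -f*(r - s + lam*(1 - exp(-s/lam))) has d/dr = -f*w
        ok = r > 1e-9
        lam = mech.drag_decay
        E -= np.sum(fmem[ok] * (r[ok] - s_pen[ok] + lam * (1.0 - w[ok])))
        G[ok, 0] -= fmem[ok] * w[ok] * X[ok, 0] / r[ok]
        G[ok, 1] -= fmem[ok] * w[ok] * X[ok, 1] / r[ok]

        # N-term lateral adhesion: radial spring to the advancing anchor
        nt_mask = self._is_nterm & ok
        if np.any(nt_mask):
            ka_nt = mech.nterm_anchor * self.node_area[nt_mask]
            dr_nt = r[nt_mask] - (r0[nt_mask] + rim_advance[nt_mask])
            E += 0.5 * float(np.sum(ka_nt * dr_nt**2))
            coef = ka_nt * dr_nt
            G[nt_mask, 0] += coef * X[nt_mask, 0] / r[nt_mask]
            G[nt_mask, 1] += coef * X[nt_mask, 1] / r[nt_mask]

        # hydrophobic matching: depth tethers that compress with thinning
        hr = 1.0 / (1.0 + sigma_star / mech.areal_modulus)
        kz = mech.z_confinement * self.node_area
        dz = X[:, 2] - self.depth_tags * hr
        E += 0.5 * float(np.sum(kz * dz**2))
        G[:, 2] += kz * dz

        # vdW adhesion to the dilated lipid inner surface
        law, Egpa = mech.vdw, mech.young_modulus_gpa
        mask = self.vdw_area > 0
        if np.any(mask):
            rm = self.vdw_rtag[mask] + self._rim_advance(sigma_star)[mask]
            gap = rm - r[mask] - ROD_DIAMETER / 2.0
            a = self.vdw_area[mask]
            gmin = self._yield_gap()
            inner = gap < gmin
            g_eff = np.where(inner, gmin, np.maximum(gap, 1e-9))
            W = vdw_energy(g_eff, law, Egpa)
            S = vdw_traction(g_eff, law, Egpa)
            # C1 linear continuation below the yield gap (compliant rim)
            W = np.where(inner, W + S * (gap - gmin), W)
            E += np.sum(a * W)
            # dE/dr = a * dW/dgap * (-1) => force = +a*S outward
            coef = a * S
            idx = np.where(mask)[0]
            okm = r[idx] > 1e-9
            G[idx[okm], 0] -= coef[okm] * X[idx[okm], 0] / r[idx[okm]]
            G[idx[okm], 1] -= coef[okm] * X[idx[okm], 1] / r[idx[okm]]

        # soft centroid tether removes the rigid-translation null space
        k_t = 1e-6
        c = X.mean(axis=0) - self.centroid0
        E += 0.5 * k_t * self.n_nodes * float(c @ c)
        G += k_t * c[None, :]

        return E, G.ravel()


def _angle_between(e1: np.ndarray, e2: np.ndarray) -> float:
    c = float(e1 @ e2 / (np.linalg.norm(e1) * np.linalg.norm(e2)))
    return math.acos(max(-1.0, min(1.0, c)))


def _bend_energy(X, triples, c):
    e1 = X[triples[:, 1]] - X[triples[:, 0]]
    e2 = X[triples[:, 2]] - X[triples[:, 1]]
    n1 = np.linalg.norm(e1, axis=1)
    n2 = np.linalg.norm(e2, axis=1)
    dot = np.einsum("ij,ij->i", e1, e2)
    cth = np.clip(dot / (n1 * n2), -1.0, 1.0)
    E = float(np.sum(c * (1.0 - cth)))
    # d(cos)/de1, d(cos)/de2
    d1 = e2 / (n1 * n2)[:, None] - (cth / n1**2)[:, None] * e1
    d2 = e1 / (n1 * n2)[:, None] - (cth / n2**2)[:, None] * e2
    G = np.zeros_like(X)
    np.add.at(G, triples[:, 0], c[:, None] * d1)
    np.add.at(G, triples[:, 1], -c[:, None] * d1 + c[:, None] * d2)
    np.add.at(G, triples[:, 2], -c[:, None] * d2)
    return E, G


def _quad_angle_energy(X, quads, c, theta0):
    e1 = X[quads[:, 1]] - X[quads[:, 0]]
    e2 = X[quads[:, 3]] - X[quads[:, 2]]
    n1 = np.linalg.norm(e1, axis=1)
    n2 = np.linalg.norm(e2, axis=1)
    cth = np.clip(np.einsum("ij,ij->i", e1, e2) / (n1 * n2), -1.0, 1.0)
    th = np.arccos(cth)
    dth = th - theta0
    E = float(np.sum(0.5 * c * dth**2))
    sth = np.sqrt(np.maximum(1.0 - cth**2, 1e-12))
    pref = -c * dth / sth  # dE/d(cos)
    d1 = e2 / (n1 * n2)[:, None] - (cth / n1**2)[:, None] * e1
    d2 = e1 / (n1 * n2)[:, None] - (cth / n2**2)[:, None] * e2
    G = np.zeros_like(X)
    np.add.at(G, quads[:, 0], -pref[:, None] * d1)
    np.add.at(G, quads[:, 1], pref[:, None] * d1)
    np.add.at(G, quads[:, 2], -pref[:, None] * d2)
    np.add.at(G, quads[:, 3], pref[:, None] * d2)
    return E, G


def _table_force(table, ext: float) -> float:
    tab = np.asarray(table, dtype=float)
    s = math.copysign(1.0, ext)
    return s * float(np.interp(abs(ext), tab[:, 0], tab[:, 1]))


def _table_energy(table, ext: float) -> float:
    tab = np.asarray(table, dtype=float)
    x = abs(ext)
    grid = np.linspace(0.0, x, 64)
    return float(np.trapezoid(np.interp(grid, tab[:, 0], tab[:, 1]), grid))


def assemble_system(
    model: ChannelModel,
    config: SolverConfig | None = None,
    mech: MechanicsParams | None = None,
) -> AssembledSystem:
    """Discretize the channel model under the given solver configuration.

    Helix-helix elastic interactions are deliberately absent: only membrane
    loads, adhesion, hinges and loop springs act between rods.
    """
    return AssembledSystem(model, config or SolverConfig(), mech or MechanicsParams())


def _solve_increment(
    system: AssembledSystem, x0: np.ndarray, sigma: float
) -> tuple[np.ndarray, bool, float]:
    cfg = system.config
    res = minimize(
        system.energy_grad,
        x0,
        args=(sigma,),
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": cfg.max_iterations,
            "gtol": cfg.tolerance,
            "ftol": 1e-16,
            "maxcor": 30,
        },
    )
    gnorm = float(np.max(np.abs(res.jac)))
    return res.x, gnorm <= cfg.tolerance * 1.001, gnorm


def solve_quasistatic(system: AssembledSystem, config: SolverConfig | None = None) -> Trajectory:
    """Incremental continuation over the sigma* schedule.

    Each increment starts from the previous solution; on non-convergence the
    increment is halved (up to ``max_halvings``).  If an increment still
    fails, a truncated trajectory is returned with diagnostics — mirroring
    the loss of stability of the N-terminus-deleted channel at high load.
    """
    cfg = config or system.config
    x = system.X0.ravel().copy()
    states: list[SystemState] = []
    patch = BilayerPatch(
        inner_radius=25.0,
        outer_radius=200.0,
        rest_thickness=system.mech.rest_thickness,
        areal_modulus=system.mech.areal_modulus,
    )
    sigma_prev = 0.0
    for sigma in cfg.increments:
        target, reached = sigma, False
        for attempt in range(cfg.max_halvings + 1):
            n_sub = 2**attempt
            xs = x.copy()
            sub_ok = True
            for sub in np.linspace(sigma_prev, target, n_sub + 1)[1:]:
                xs, ok, gnorm = _solve_increment(system, xs, float(sub))
                if not ok:
                    sub_ok = False
                    break
            if sub_ok:
                x, reached = xs, True
                break
        stretch = 1.0 + sigma / system.mech.areal_modulus
        _, thin = thinning_response(patch, stretch)
        if not reached:
            traj = Trajectory(
                states,
                completed=False,
                diagnostic=(
                    f"lost stability at sigma*={sigma:.4g}: residual {gnorm:.3g} "
                    f"after {cfg.max_halvings} halvings"
                ),
            )
            return traj
        X = x.reshape(-1, 3)
        stress = _element_von_mises(system, X)
        states.append(
            SystemState(float(sigma), X.copy(), True, gnorm, thin, stress)
        )
        sigma_prev = float(sigma)
    return Trajectory(states, completed=True)


def _element_von_mises(system: AssembledSystem, X: np.ndarray) -> np.ndarray:
    """Outer-fiber equivalent stress per segment from axial + bending resultants."""
    e = X[system.segments[:, 1]] - X[system.segments[:, 0]]
    ln = np.linalg.norm(e, axis=1)
    N = system.seg_ka * (ln - system.seg_rest)  # axial force, E*A^2
    sig_ax = np.abs(N) / ROD_AREA
    # bending moment at each interior joint -> map to adjacent segments
    m_node = np.zeros(system.n_nodes)
    if len(system.bends):
        e1 = X[system.bends[:, 1]] - X[system.bends[:, 0]]
        e2 = X[system.bends[:, 2]] - X[system.bends[:, 1]]
        cth = np.clip(
            np.einsum("ij,ij->i", e1, e2)
            / (np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)),
            -1.0,
            1.0,
        )
        theta = np.arccos(cth)
        np.maximum.at(m_node, system.bends[:, 1], system.bend_c * theta)
    m_seg = np.maximum(m_node[system.segments[:, 0]], m_node[system.segments[:, 1]])
    sig_bend = m_seg * (ROD_DIAMETER / 2.0) / ROD_INERTIA
    return sig_ax + sig_bend


def von_mises_map(system: AssembledSystem, state: SystemState) -> dict[str, np.ndarray]:
    """Per-segment equivalent stress grouped by helix class.

    Requires a converged state; stresses are dimensionless (stress/E).
    """
    if not state.converged:
        raise ValueError("von Mises map requires a converged state")
    out: dict[str, list[float]] = {}
    for s, cls in zip(state.element_stress, system.seg_class):
        out.setdefault(cls, []).append(float(s))
    return {k: np.asarray(v) for k, v in out.items()}


def mesh_sensitivity(
    model: ChannelModel,
    config: SolverConfig | None = None,
    mech: MechanicsParams | None = None,
    levels: tuple[int, ...] = (4, 8, 16),
) -> dict:
    """Key gating metrics versus nodes-per-helix refinement.

    Reports TM1 tilt and effective pore radius at the final converged
    increment for each level and the coarsest level whose metrics change by
    less than 2% upon refinement.
    """
    from .metrics import effective_pore_radius, tilt_to_axis

    if len(levels) < 3:
        raise ValueError("mesh sensitivity needs at least 3 refinement levels")
    cfg = config or SolverConfig()
    rows = []
    for n in levels:
        level_cfg = replace(cfg, nodes_per_helix=int(n))
        system = assemble_system(model, level_cfg, mech)
        traj = solve_quasistatic(system)
        tilt, _ = tilt_to_axis(system, traj.final, "TM1")
        pore = effective_pore_radius(system, traj.final)
        rows.append({"nodes_per_helix": int(n), "tm1_tilt_deg": tilt, "pore_radius_A": pore})
    converged_at = None
    for a, b in zip(rows, rows[1:]):
        dt = abs(b["tm1_tilt_deg"] - a["tm1_tilt_deg"]) / max(abs(a["tm1_tilt_deg"]), 1e-9)
        dp = abs(b["pore_radius_A"] - a["pore_radius_A"]) / max(abs(a["pore_radius_A"]), 1e-9)
        if dt < 0.02 and dp < 0.02 and converged_at is None:
            converged_at = a["nodes_per_helix"]
    return {"levels": rows, "converged_at_nodes_per_helix": converged_at}


# ---------------------------------------------------------------------------
# closed-form benchmarks for the rod formulation
# ---------------------------------------------------------------------------

class _ChainSystem:
    """Minimal straight-rod system for beam benchmarks (clamped end)."""

    def __init__(self, n_elements: int, length: float, diameter: float = ROD_DIAMETER):
        self.n = n_elements + 1
        self.L = length
        le = length / n_elements
        self.le = le
        self.X0 = np.zeros((self.n, 3))
        self.X0[:, 0] = np.linspace(0.0, length, self.n)
        self.ka = ROD_AREA / le * (diameter / ROD_DIAMETER) ** 2
        area = math.pi * diameter**2 / 4.0
        inertia = math.pi * diameter**4 / 64.0
        self.ka = area / le
        self.EI = inertia
        # Voronoi-weighted curvature springs: l/2 at the clamped wall joint
        self.bend_nodes = list(range(1, self.n - 1))
        self.c_int = inertia / le
        self.c_wall = inertia / (le / 2.0)

    def energy_grad(self, u: np.ndarray, tip_load: np.ndarray):
        X = self.X0.copy()
        X[1:] = u.reshape(-1, 3)  # node 0 clamped at the origin
        G = np.zeros_like(X)
        E = 0.0
        e = X[1:] - X[:-1]
        ln = np.linalg.norm(e, axis=1)
        rest = self.le
        stretch = ln - rest
        E += 0.5 * self.ka * np.sum(stretch**2)
        f = (self.ka * stretch / ln)[:, None] * e
        G[:-1] -= f
        G[1:] += f
        triples = np.array([(i - 1, i, i + 1) for i in self.bend_nodes], dtype=int)
        if len(triples):
            Eb, Gb = _bend_energy(X, triples, np.full(len(triples), self.c_int))
            E += Eb
            G += Gb
        # wall clamp: angle between the fixed -x ghost direction and segment 0
        ghost = np.array([[-self.le, 0.0, 0.0], [0.0, 0.0, 0.0]])
        Xw = np.vstack([ghost, X[1][None, :]])
        Ew, Gw = _bend_energy(Xw, np.array([[0, 1, 2]]), np.array([self.c_wall]))
        E += Ew
        G[0] += Gw[1]
        G[1] += Gw[2]
        E -= float(tip_load @ X[-1])
        G[-1] -= tip_load
        return E, G[1:].ravel()


def cantilever_tip_deflection(
    n_elements: int = 10,
    length: float = 50.0,
    diameter: float = ROD_DIAMETER,
    load: float = 1e-4,
) -> tuple[float, float]:
    """Transverse tip deflection of a clamped rod vs the P L^3 / 3EI closed form.

    Small-load regime; returns ``(computed, euler_bernoulli)`` in A.
    """
    chain = _ChainSystem(n_elements, length, diameter)
    P = np.array([0.0, load, 0.0])
    res = minimize(
        chain.energy_grad,
        chain.X0[1:].ravel(),
        args=(P,),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 20000, "gtol": 1e-14, "ftol": 1e-18},
    )
    tip = res.x.reshape(-1, 3)[-1]
    closed = load * length**3 / (3.0 * chain.EI)
    return float(tip[1]), closed


def axial_bar_force(stretch_displacement: float, length: float = 30.0) -> tuple[float, float]:
    """Axial force of a uniformly stretched rod vs EA*u/L (exact for springs)."""
    ka = ROD_AREA / length
    return ka * stretch_displacement, ROD_AREA * stretch_displacement / length
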