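"""Coarse-grained channel geometry: helix axes, angles, and pentamer builds.

The channel is reduced to straight elastic-rod segments, one per helix
(N-terminal interfacial helix, pore-lining TM1, lipid-facing TM2, for each of
the five subunits).  Geometry comes either from a PDB structure (total-least-
squares axis fits to C-alpha coordinates) or from an idealized C5-symmetric
construction that realizes a requested set of crossing angles and distances.

Coordinate frame: the fivefold symmetry axis is +z, the membrane midplane is
z = 0, and the periplasmic side is +z.

Angle conventions (the literature mixes two, so both are exposed):

* :func:`interhelix_angle` — plain arccos of the two N->C direction vectors,
  unsigned, in [0, 180].  This is the convention under which the closed-state
  N-term/TM1 link reads ~95 deg and TM1/TM2 pairs read ~135 / ~169 deg.
* :func:`crossing_angle` — signed packing angle: the torsion of axis b
  relative to axis a about their closest-approach connector, folded into
  (-90, 90].  Positive when b is reached from a by a right-handed rotation
  about the connector directed a -> b.  This is the convention under which
  adjacent TM1 helices read ~-43 deg and the adjacent TM1/TM2 pair ~+10 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HelixSegment",
    "HingeSpec",
    "LoopSpring",
    "ChannelModel",
    "IdealizedParams",
    "DEFAULT_SEGMENT_TABLE",
    "fit_helix_axis",
    "crossing_angle",
    "closest_approach",
    "interhelix_angle",
    "build_from_structure",
    "build_idealized",
    "measure_model",
    "write_ca_pdb",
    "rotate_z",
]

HELIX_RISE = 1.5  # A per residue, ideal alpha-helix
HELIX_TWIST = 100.0  # deg per residue
HELIX_RADIUS = 2.3  # A, C-alpha radius of an ideal alpha-helix

#: Conventional MscL-like residue assignments (1-based, inclusive); a
#: configurable default, not hard-coded truth.
DEFAULT_SEGMENT_TABLE: dict[str, tuple[int, int]] = {
    "NTERM": (1, 13),
    "TM1": (15, 43),
    "TM2": (69, 93),
}


class DegenerateGeometryError(ValueError):
    """Raised for inputs that do not define a usable axis."""


@dataclass(frozen=True)
class HelixSegment:
    """A helix reduced to a finite straight rod.

    ``axis_point`` is the N-terminal endpoint of the rod; the segment runs to
    ``axis_point + length * axis_direction`` with ``axis_direction`` oriented
    from the N-terminal to the C-terminal end.
    """

    subunit_index: int
    name: str  # NTERM | TM1 | TM2
    residue_range: tuple[int, int]
    axis_point: np.ndarray
    axis_direction: np.ndarray
    length: float
    rod_diameter: float = 5.0

    def __post_init__(self) -> None:
        if self.name not in ("NTERM", "TM1", "TM2"):
            raise ValueError(f"unknown helix name {self.name!r}")
        if not 0 <= self.subunit_index <= 4:
            raise ValueError("subunit_index must be in 0..4")
        if self.residue_range[0] > self.residue_range[1]:
            raise ValueError("residue_range start must be <= end")
        if self.length <= 0 or self.rod_diameter <= 0:
            raise ValueError("length and rod_diameter must be positive")
        d = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float))
        object.__setattr__(self, "axis_direction", d)

    @property
    def start(self) -> np.ndarray:
        return self.axis_point

    @property
    def end(self) -> np.ndarray:
        return self.axis_point + self.length * self.axis_direction

    @property
    def midpoint(self) -> np.ndarray:
        return self.axis_point + 0.5 * self.length * self.axis_direction

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "HelixSegment":
        return replace(
            self,
            axis_point=R @ self.axis_point + t,
            axis_direction=R @ self.axis_direction,
        )


@dataclass(frozen=True)
class HingeSpec:
    """Flexible G14-like joint between NTERM and TM1 of one subunit.

    ``rotational_stiffness`` is dimensionless (ratio to the rod bending
    stiffness); 0 is an ideally free hinge.  ``linker_extension_residues``
    inserts that many extra backbone residues (+2G, +5G constructs).
    """

    subunit_index: int
    location: np.ndarray
    free_axis: np.ndarray
    rotational_stiffness: float = 0.0
    linker_extension_residues: int = 0

    def __post_init__(self) -> None:
        if self.rotational_stiffness < 0:
            raise ValueError("rotational_stiffness must be >= 0")
        if not 0 <= self.linker_extension_residues <= 10:
            raise ValueError("linker_extension_residues must be in 0..10")
        a = np.asarray(self.free_axis, dtype=float)
        n = np.linalg.norm(a)
        if n < 1e-12:
            raise ValueError("free_axis must be nonzero")
        object.__setattr__(self, "free_axis", a / n)
        object.__setattr__(self, "location", np.asarray(self.location, dtype=float))


@dataclass(frozen=True)
class LoopSpring:
    """Nonlinear-wire stand-in for an inter-helix loop.

    ``endpoints`` are (subunit, helix name, 'start'|'end') references.  The
    optional force-extension table (extension in A, force dimensionless) must
    be monotone and pass through (0, 0); when absent the solver uses its
    default linear law.
    """

    endpoints: tuple[tuple[int, str, str], tuple[int, str, str]]
    force_extension_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.force_extension_table is not None:
            tab = np.asarray(self.force_extension_table, dtype=float)
            ext, frc = tab[:, 0], tab[:, 1]
            if not (np.all(np.diff(ext) > 0) and np.all(np.diff(frc) >= 0)):
                raise ValueError("force-extension table must be monotone")
            if not np.any(np.all(np.isclose(tab, 0.0), axis=1)):
                raise ValueError("force-extension table must pass through (0, 0)")


@dataclass
class ChannelModel:
    """Pentameric rod assembly: 5 x (NTERM, TM1, TM2) plus hinges and loops."""

    helices: list[HelixSegment]
    hinges: list[HingeSpec]
    loops: list[LoopSpring]
    has_nterm: bool = True
    symmetry_order: int = 5

    def __post_init__(self) -> None:
        if not self.has_nterm:
            if any(h.name == "NTERM" for h in self.helices) or self.hinges:
                raise ValueError("has_nterm=False model must have no NTERM segments or hinges")

    def get(self, subunit: int, name: str) -> HelixSegment:
        for h in self.helices:
            if h.subunit_index == subunit and h.name == name:
                return h
        raise KeyError(f"no helix {name} in subunit {subunit}")

    def by_name(self, name: str) -> list[HelixSegment]:
        return [h for h in self.helices if h.name == name]

    def node_cloud(self, per_segment: int = 9) -> np.ndarray:
        t = np.linspace(0.0, 1.0, per_segment)
        pts = [h.start[None, :] + t[:, None] * (h.end - h.start)[None, :] for h in self.helices]
        return np.concatenate(pts, axis=0)


# ---------------------------------------------------------------------------
# measurement operations
# ---------------------------------------------------------------------------

def fit_helix_axis(backbone_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line through backbone coordinates.

    Returns ``(axis_point, axis_direction, length)``: the N-end foot point,
    the unit direction oriented from the first toward the last coordinate,
    and the span of the coordinate projections onto the axis.
    """
    X = np.asarray(backbone_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise DegenerateGeometryError("expected an (n, 3) coordinate array")
    if X.shape[0] < 4:
        raise DegenerateGeometryError("helix axis fit needs at least 4 coordinates")
    centroid = X.mean(axis=0)
    Y = X - centroid
    if np.max(np.linalg.norm(Y, axis=1)) < 1e-9:
        raise DegenerateGeometryError("coincident coordinates do not define an axis")
    # principal direction of the scatter = TLS line direction
    _, _, vt = np.linalg.svd(Y, full_matrices=False)
    d = vt[0]
    if d @ (X[-1] - X[0]) < 0:
        d = -d
    proj = Y @ d
    length = float(proj.max() - proj.min())
    if length < 1e-9:
        raise DegenerateGeometryError("zero projection span: degenerate axis")
    start = centroid + proj.min() * d
    return start, d, length


def _unit(v: np.ndarray, what: str = "axis") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


def interhelix_angle(a: HelixSegment, b: HelixSegment) -> float:
    """Unsigned angle in [0, 180] between the two N->C direction vectors."""
    da, db = _unit(a.axis_direction), _unit(b.axis_direction)
    return math.degrees(math.acos(np.clip(da @ db, -1.0, 1.0)))


def _segment_closest_points(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closest points between finite segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    b, c = d1 @ d2, d1 @ r
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0.0 or t > 1.0:
        t = np.clip(t, 0.0, 1.0)
        s = np.clip((b * t - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return p1 + s * d1, p2 + t * d2


def closest_approach(a: HelixSegment, b: HelixSegment) -> float:
    """Minimum Euclidean distance between the two finite rod centerlines."""
    pa, pb = _segment_closest_points(a.start, a.end, b.start, b.end)
    return float(np.linalg.norm(pa - pb))


def crossing_angle(a: HelixSegment, b: HelixSegment) -> float:
    """Signed helix-packing crossing angle, folded into (-90, 90].

    Magnitude: the line-crossing angle between the two axes (inter-axis angle
    folded to at most 90 deg).  Sign: handedness of the packing, positive when
    b's axis is reached from a's by a right-handed rotation about the
    closest-approach connector directed a -> b; symmetric in its arguments.
    """
    da, db = _unit(a.axis_direction), _unit(b.axis_direction)
    ang = interhelix_angle(a, b)
    folded = ang if ang <= 90.0 else 180.0 - ang
    pa, pb = _segment_closest_points(a.start, a.end, b.start, b.end)
    u = pb - pa
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        return folded  # intersecting axes: no packing handedness
    u = u / nu
    ap = da - (da @ u) * u
    bp = db - (db @ u) * u
    if np.linalg.norm(ap) < 1e-9 or np.linalg.norm(bp) < 1e-9:
        raise DegenerateGeometryError("axis parallel to the connector: crossing angle undefined")
    omega = math.degrees(math.atan2(np.cross(ap, bp) @ u, ap @ bp))
    # fold the torsion to a line-pair handedness in (-90, 90]
    if omega > 90.0:
        omega -= 180.0
    elif omega <= -90.0:
        omega += 180.0
    return math.copysign(folded, omega) if omega != 0.0 else folded


# ---------------------------------------------------------------------------
# construction from a structure file
# ---------------------------------------------------------------------------

def _read_ca_coords(structure_file: str | Path) -> dict[str, dict[int, np.ndarray]]:
    """C-alpha coordinates per chain, first model only, altloc '' or 'A'."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("channel", str(structure_file))
    model = next(structure.get_models())
    out: dict[str, dict[int, np.ndarray]] = {}
    for chain in model:
        coords: dict[int, np.ndarray] = {}
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM / waters
                continue
            for atom in residue:
                if atom.get_name() == "CA" and atom.get_altloc() in (" ", "", "A"):
                    coords[residue.id[1]] = np.asarray(atom.get_coord(), dtype=float)
                    break
        if coords:
            out[chain.id] = coords
    return out


def build_from_structure(
    structure_file: str | Path,
    segment_table: dict[str, tuple[int, int]] | None = None,
    chains: str = "ABCDE",
    rod_diameter: float = 5.0,
    has_nterm: bool = True,
) -> ChannelModel:
    """Fit one rod per declared helix range in each chain of a PDB file.

    ``segment_table`` maps helix names to 1-based inclusive residue ranges;
    missing residues raise an error that names every gap.
    """
    table = dict(segment_table or DEFAULT_SEGMENT_TABLE)
    if not has_nterm:
        table.pop("NTERM", None)
    ca = _read_ca_coords(structure_file)
    missing_chains = [c for c in chains if c not in ca]
    if missing_chains:
        raise ValueError(f"chains missing from {structure_file}: {missing_chains}")
    helices: list[HelixSegment] = []
    gaps: list[str] = []
    for si, chain_id in enumerate(chains):
        coords = ca[chain_id]
        for name, (lo, hi) in table.items():
            absent = [r for r in range(lo, hi + 1) if r not in coords]
            if absent:
                gaps.append(f"chain {chain_id} {name} residues {absent}")
                continue
            pts = np.array([coords[r] for r in range(lo, hi + 1)])
            start, d, length = fit_helix_axis(pts)
            helices.append(
                HelixSegment(si, name, (lo, hi), start, d, length, rod_diameter)
            )
    if gaps:
        raise ValueError("missing residues: " + "; ".join(gaps))
    hinges, loops = _connectors_for(helices, chains=len(chains), has_nterm=has_nterm)
    return ChannelModel(helices, hinges, loops, has_nterm=has_nterm, symmetry_order=len(chains))


def _connectors_for(
    helices: list[HelixSegment], chains: int, has_nterm: bool
) -> tuple[list[HingeSpec], list[LoopSpring]]:
    by = {(h.subunit_index, h.name): h for h in helices}
    hinges, loops = [], []
    for si in range(chains):
        if has_nterm and (si, "NTERM") in by and (si, "TM1") in by:
            junction = 0.5 * (by[(si, "NTERM")].end + by[(si, "TM1")].start)
            free = np.cross(by[(si, "NTERM")].axis_direction, by[(si, "TM1")].axis_direction)
            if np.linalg.norm(free) < 1e-9:
                free = np.array([0.0, 0.0, 1.0])
            hinges.append(HingeSpec(si, junction, free))
        if (si, "TM1") in by and (si, "TM2") in by:
            loops.append(LoopSpring(((si, "TM1", "end"), (si, "TM2", "start"))))
    return hinges, loops


# ---------------------------------------------------------------------------
# idealized C5-symmetric build
# ---------------------------------------------------------------------------

def rotate_z(angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class IdealizedParams:
    """Target geometry for the idealized closed-state pentamer.

    Angles follow the conventions documented at module level: ``cross_*`` are
    signed folded packing angles, ``angle_*`` plain inter-axis angles.
    Lengths use the (n_res - 1) * 1.5 A helical-span convention.
    """

    cross_tm1_tm1_adj: float = -43.0
    angle_tm1_tm2_same: float = 135.0
    angle_tm1_tm2_adj: float = 169.0
    gap_tm2_tm2_adj: float = 20.0
    angle_nterm_tm1: float = 95.0
    contact_tm1_tm2_adj: float = 5.5  # A; adjacent TM1/TM2 pack in vdW contact
    pore_centerline_radius: float = 7.0  # closed-state TM1 N-end radius, A
    rod_diameter: float = 5.0
    tm1_range: tuple[int, int] = (15, 43)
    tm2_range: tuple[int, int] = (69, 93)
    nterm_range: tuple[int, int] = (1, 13)
    tm1_bottom_z: float = -16.5
    tm1_tilt_azimuth: float = 25.0  # deg; splits TM1 tilt into radial/tangential
    tm2_mid_z: float = 0.0
    tm1_tilt_prior: float = 28.0  # deg; weakly preferred closed TM1 tilt-to-axis

    def helix_length(self, name: str) -> float:
        lo, hi = {"TM1": self.tm1_range, "TM2": self.tm2_range, "NTERM": self.nterm_range}[name]
        return (hi - lo) * HELIX_RISE


def _direction(theta_deg: float, azimuth_deg: float, down: bool = False) -> np.ndarray:
    th, az = math.radians(theta_deg), math.radians(azimuth_deg)
    z = -math.cos(th) if down else math.cos(th)
    return np.array([math.sin(th) * math.cos(az), math.sin(th) * math.sin(az), z])


def _subunit_zero(params: IdealizedParams, x: np.ndarray) -> dict[str, HelixSegment]:
    """Build subunit-0 segments from the free-parameter vector ``x``.

    x = (tm1_tilt, tm2_tilt, tm2_dir_azimuth, tm2_mid_radius, tm2_mid_azimuth,
         nterm_azimuth, nterm_dip)
    """
    t1, t2, phi2, r2, a2, bn, dip = x
    d1 = _direction(t1, params.tm1_tilt_azimuth)
    b1 = np.array([params.pore_centerline_radius, 0.0, params.tm1_bottom_z])
    tm1 = HelixSegment(0, "TM1", params.tm1_range, b1, d1,
                       params.helix_length("TM1"), params.rod_diameter)
    d2 = _direction(t2, phi2, down=True)
    m2 = np.array([r2 * math.cos(math.radians(a2)), r2 * math.sin(math.radians(a2)),
                   params.tm2_mid_z])
    L2 = params.helix_length("TM2")
    tm2 = HelixSegment(0, "TM2", params.tm2_range, m2 - 0.5 * L2 * d2, d2, L2,
                       params.rod_diameter)
    dn = _direction(90.0 + dip, bn)
    Ln = params.helix_length("NTERM")
    nterm = HelixSegment(0, "NTERM", params.nterm_range, b1 - Ln * dn, dn, Ln,
                         params.rod_diameter)
    return {"TM1": tm1, "TM2": tm2, "NTERM": nterm}


def _idealized_residuals(x: np.ndarray, params: IdealizedParams) -> np.ndarray:
    s0 = _subunit_zero(params, x)
    s1 = {k: h.transformed(rotate_z(72.0), np.zeros(3)) for k, h in s0.items()}
    # TM2 of the previous (i-1) subunit is the adjacent-contact partner of TM1
    s4 = {k: h.transformed(rotate_z(-72.0), np.zeros(3)) for k, h in s0.items()}
    res = [
        crossing_angle(s0["TM1"], s1["TM1"]) - params.cross_tm1_tm1_adj,
        interhelix_angle(s0["TM1"], s0["TM2"]) - params.angle_tm1_tm2_same,
        interhelix_angle(s0["TM1"], s4["TM2"]) - params.angle_tm1_tm2_adj,
        closest_approach(s0["TM2"], s1["TM2"]) - params.gap_tm2_tm2_adj,
        interhelix_angle(s0["NTERM"], s0["TM1"]) - params.angle_nterm_tm1,
        # soft constraints: adjacent TM1/TM2 stay in packing contact, and the
        # remaining placement freedom is pinned by weak regularizers
        0.3 * (closest_approach(s0["TM1"], s4["TM2"]) - params.contact_tm1_tm2_adj),
        0.05 * (x[0] - params.tm1_tilt_prior),
        0.02 * (x[6] - 5.0),
    ]
    return np.asarray(res)


def build_idealized(params: IdealizedParams | None = None, has_nterm: bool = True) -> ChannelModel:
    """Deterministic exact-C5 pentamer realizing the requested geometry.

    The five free placement parameters are solved by damped least squares
    from a fixed starting point, so the construction involves no randomness.
    Raises if the requested angle/distance combination cannot be realized to
    within 0.5 deg / 0.5 A.
    """
    params = params or IdealizedParams()
    x0 = np.array([38.0, 34.0, 330.0, 16.0, 0.0, 150.0, 5.0])
    sol = least_squares(_idealized_residuals, x0, args=(params,), xtol=1e-14, ftol=1e-14)
    hard = sol.fun[:5]
    if np.any(np.abs(hard[[0, 1, 2, 4]]) > 0.5) or abs(hard[3]) > 0.5:
        raise ValueError(
            "idealized geometry infeasible: residuals "
            f"angles={hard[[0, 1, 2, 4]].round(3)} deg, gap={hard[3]:.3f} A"
        )
    s0 = _subunit_zero(params, sol.x)
    helices: list[HelixSegment] = []
    for si in range(5):
        R = rotate_z(72.0 * si)
        for name in ("NTERM", "TM1", "TM2"):
            if name == "NTERM" and not has_nterm:
                continue
            helices.append(replace(s0[name].transformed(R, np.zeros(3)), subunit_index=si))
    hinges, loops = _connectors_for(helices, chains=5, has_nterm=has_nterm)
    return ChannelModel(helices, hinges, loops, has_nterm=has_nterm)


def measure_model(model: ChannelModel) -> dict[str, float]:
    """Standard closed-state report: the printed crossing angles and gaps."""
    g = model.get
    out = {
        "cross_tm1_tm1_adj": crossing_angle(g(0, "TM1"), g(1, "TM1")),
        "angle_tm1_tm2_same": interhelix_angle(g(0, "TM1"), g(0, "TM2")),
        "angle_tm1_tm2_adj": interhelix_angle(g(0, "TM1"), g(4, "TM2")),
        "cross_tm1_tm2_adj": crossing_angle(g(0, "TM1"), g(4, "TM2")),
        "gap_tm2_tm2_adj": closest_approach(g(0, "TM2"), g(1, "TM2")),
        "tm1_tilt_to_axis": math.degrees(
            math.acos(abs(np.clip(g(0, "TM1").axis_direction[2], -1, 1)))
        ),
        "tm2_tilt_to_axis": math.degrees(
            math.acos(abs(np.clip(g(0, "TM2").axis_direction[2], -1, 1)))
        ),
    }
    if model.has_nterm:
        out["angle_nterm_tm1"] = interhelix_angle(g(0, "NTERM"), g(0, "TM1"))
    return out


# ---------------------------------------------------------------------------
# minimal PDB output for fixtures and visualization
# ---------------------------------------------------------------------------

def _helix_ca_coords(seg: HelixSegment, on_axis: bool = True) -> np.ndarray:
    """Synthetic C-alpha positions along a rod, one per residue.

    With ``on_axis`` the points sit exactly on the centerline (axis fits
    round-trip exactly); otherwise they coil around it at the ideal helical
    radius with 100 deg/residue twist.
    """
    lo, hi = seg.residue_range
    n = hi - lo + 1
    t = np.linspace(0.0, 1.0, n)
    pts = seg.start[None, :] + t[:, None] * (seg.end - seg.start)[None, :]
    if not on_axis:
        d = seg.axis_direction
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = _unit(np.cross(d, ref))
        e2 = np.cross(d, e1)
        phase = np.radians(HELIX_TWIST) * np.arange(n)
        pts = pts + HELIX_RADIUS * (np.cos(phase)[:, None] * e1 + np.sin(phase)[:, None] * e2)
    return pts


def write_ca_pdb(model: ChannelModel, path: str | Path, on_axis: bool = True) -> Path:
    """Write a single-model C-alpha-only PDB (chains A..E) for the rod model."""
    path = Path(path)
    lines = []
    serial = 1
    for si in range(model.symmetry_order):
        chain = "ABCDE"[si]
        segs = sorted(
            (h for h in model.helices if h.subunit_index == si),
            key=lambda h: h.residue_range[0],
        )
        for seg in segs:
            for resseq, xyz in zip(
                range(seg.residue_range[0], seg.residue_range[1] + 1),
                _helix_ca_coords(seg, on_axis=on_axis),
            ):
                lines.append(
                    f"ATOM  {serial:5d}  CA  ALA {chain}{resseq:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      ALA {chain}{segs[-1].residue_range[1]:4d}")
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
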