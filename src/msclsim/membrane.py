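"""Bilayer continuum: lateral pressure profile, tension, and thinning.

The membrane is not meshed as a 3D solid.  It acts on the rod model through
(i) a depth-resolved lateral pressure profile whose integral carries the
applied tension, and (ii) the van der Waals adhesion law of
:mod:`msclsim.vdw`.  All stresses are dimensionless ratios to the protein
Young's modulus E, so results are independent of E's absolute value.

Sign conventions: positive lateral pressure (headgroup and acyl-tail
repulsion) pushes a membrane inclusion radially inward; negative pressure
(interfacial tension) pulls it outward.  At zero applied tension the zeroth
moment of the profile vanishes (mechanical rest); under a nondimensional
tension sigma* the integral over depth equals -sigma*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LateralPressureProfile",
    "BilayerPatch",
    "build_pressure_profile",
    "thinning_response",
    "membrane_load_on_rod",
]


@dataclass(frozen=True)
class LateralPressureProfile:
    """Piecewise-constant five-band pressure profile over depth z (A).

    Bands from the periplasmic (+z) side down: head / interface / tail /
    interface / head.  ``boundaries`` are the six z values delimiting them,
    decreasing; ``amplitudes`` the five band pressures (stress/E).
    """

    boundaries: tuple[float, float, float, float, float, float]
    amplitudes: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if not np.all(np.diff(b) < 0):
            raise ValueError("band boundaries must strictly decrease from the top")

    def pressure(self, z: np.ndarray | float) -> np.ndarray:
        """Band pressure at depth z; zero outside the membrane span."""
        z = np.asarray(z, dtype=float)
        p = np.zeros_like(z)
        b, a = self.boundaries, self.amplitudes
        for k in range(5):
            sel = (z <= b[k]) & (z > b[k + 1]) if k < 4 else (z <= b[k]) & (z >= b[k + 1])
            p = np.where(sel, a[k], p)
        return p

    def zeroth_moment(self) -> float:
        """Integral of the profile over depth (exact for piecewise-constant)."""
        b = np.asarray(self.boundaries)
        widths = -np.diff(b)
        return float(np.dot(widths, self.amplitudes))

    @property
    def span(self) -> tuple[float, float]:
        return self.boundaries[-1], self.boundaries[0]


def build_pressure_profile(
    thickness: float = 33.3,
    head_width: float = 5.0,
    interface_width: float = 4.0,
    sigma_star: float = 0.0,
    head_rest_pressure: float = 0.02,
    tail_rest_pressure: float = 0.005,
    head_tension_fraction: float = 0.5,
) -> LateralPressureProfile:
    """Five-band profile satisfying both moment constraints.

    Rest amplitudes: repulsive heads and a small repulsive tail band are
    balanced by interfacial tension so the zeroth moment is exactly zero.
    The applied tension ``sigma_star`` is then distributed between the head
    bands (fraction ``head_tension_fraction`` — the head/solvent interface)
    and the interface bands, keeping the total integral at -sigma*.  All
    tension-dependent parts are affine in sigma*.
    """
    if sigma_star < 0:
        raise ValueError("sigma_star must be >= 0")
    if head_width <= 0 or interface_width <= 0:
        raise ValueError("band widths must be positive")
    tail_width = thickness - 2 * (head_width + interface_width)
    if tail_width <= 0:
        raise ValueError("head/interface bands leave no tail band")
    h2 = thickness / 2.0
    boundaries = (
        h2,
        h2 - head_width,
        h2 - head_width - interface_width,
        -h2 + head_width + interface_width,
        -h2 + head_width,
        -h2,
    )
    # rest balance: 2*ph*wh + 2*pi*wi + pt*wt = 0
    p_int_rest = -(2 * head_rest_pressure * head_width + tail_rest_pressure * tail_width) / (
        2 * interface_width
    )
    dp_head = -head_tension_fraction * sigma_star / (2 * head_width)
    dp_int = -(1.0 - head_tension_fraction) * sigma_star / (2 * interface_width)
    amplitudes = (
        head_rest_pressure + dp_head,
        p_int_rest + dp_int,
        tail_rest_pressure,
        p_int_rest + dp_int,
        head_rest_pressure + dp_head,
    )
    return LateralPressureProfile(boundaries, amplitudes)


@dataclass
class BilayerPatch:
    """Annular membrane patch around the protein.

    ``areal_modulus`` (stress/E) converts applied tension into areal stretch,
    lambda_A = 1 + sigma*/K_A; the thickness field follows volume
    conservation with a smooth boundary layer at the protein rim.
    """

    inner_radius: float
    outer_radius: float
    rest_thickness: float = 33.3
    sigma_star: float = 0.0
    areal_modulus: float = 3.4
    boundary_layer: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.sigma_star < 0:
            raise ValueError("sigma_star must be >= 0")
        if self.rest_thickness <= 0 or self.areal_modulus <= 0:
            raise ValueError("rest_thickness and areal_modulus must be positive")

    @property
    def areal_stretch(self) -> float:
        return 1.0 + self.sigma_star / self.areal_modulus

    def thickness(self, r: np.ndarray | float) -> np.ndarray:
        return thinning_response(self, self.areal_stretch)[0](np.asarray(r, dtype=float))

    @property
    def far_thickness(self) -> float:
        return self.rest_thickness / self.areal_stretch


def thinning_response(patch: BilayerPatch, areal_stretch: float):
    """Volume-conserving thinning: far field h = h0/lambda_A plus rim layer.

    Returns ``(h_of_r, thinning_pct)``: a callable thickness field and the
    far-field percent thinning 100*(1 - h/h0).  Near the protein the
    thickness relaxes back toward its rest value over ``boundary_layer`` A
    (hydrophobic matching at the rim).
    """
    if areal_stretch < 1.0:
        raise ValueError("areal compression (stretch < 1) is out of scope")
    h0 = patch.rest_thickness
    h_far = h0 / areal_stretch

    def h_of_r(r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        decay = np.exp(-np.maximum(r - patch.inner_radius, 0.0) / patch.boundary_layer)
        return h_far + (h0 - h_far) * decay

    thinning_pct = 100.0 * (1.0 - h_far / h0)
    return h_of_r, thinning_pct


def membrane_load_on_rod(
    profile: LateralPressureProfile,
    node_positions: np.ndarray,
    node_depths: np.ndarray,
    node_areas: np.ndarray,
) -> np.ndarray:
    """Distributed lateral load on rod nodes from the pressure profile.

    ``node_depths`` are the material membrane-depth tags assigned at
    assembly; ``node_areas`` the tributary side areas (A^2, already scaled by
    lipid exposure).  Each node inside the membrane span receives the band
    pressure at its tagged depth, directed radially: positive pressure pushes
    toward the pore axis, negative (tension-carrying) pressure pulls outward.
    Nodes outside the span receive zero.
    """
    X = np.asarray(node_positions, dtype=float)
    z = np.asarray(node_depths, dtype=float)
    a = np.asarray(node_areas, dtype=float)
    if X.shape[0] != z.shape[0] or X.shape[0] != a.shape[0]:
        raise ValueError("node positions, depths and areas must align")
    if np.any(np.isnan(z)):
        raise ValueError("untagged (NaN-depth) nodes in membrane load evaluation")
    p = profile.pressure(z)
    r = np.linalg.norm(X[:, :2], axis=1)
    rhat = np.zeros_like(X)
    ok = r > 1e-9
    rhat[ok, 0] = X[ok, 0] / r[ok]
    rhat[ok, 1] = X[ok, 1] / r[ok]
    return (-p * a)[:, None] * rhat
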