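"""Lipid-helix van der Waals surface traction and Hamaker-constant fitting.

The lipid bilayer inner surface (master) and the outer surface of each TM
helix (slave) interact through a Hamaker-type surface stress with a 3-9
attraction/repulsion pair,

    S(D) = A_H / (6 pi D0^3) * [ (D0/D)^3 - (D0/D)^9 ],

zero at the equilibrium separation D0, positive (attractive) for D > D0 and
negative (repulsive) for D < D0.  The exponent pair is configurable.  The
corresponding interaction energy per unit contact area is the integral of
the traction, with its minimum -A_H / (16 pi D0^2) at D0 for the (3, 9)
pair.  Tractions are nondimensionalized by the protein Young's modulus E;
with A_H in zeptojoules and distances in Angstrom, A_H / (6 pi D0^3) is in
gigapascal, so S* = S / E_GPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "VdwLaw",
    "EnergyDistanceTable",
    "DEFAULT_YOUNG_MODULUS_GPA",
    "vdw_traction",
    "vdw_energy",
    "fit_hamaker",
    "generate_energy_table",
    "assemble_contact_tractions",
]

#: Reference protein Young's modulus used to nondimensionalize tractions.
#: Soft-protein continuum scale; every output that matters is a ratio to E.
DEFAULT_YOUNG_MODULUS_GPA = 0.2

# Unit bridge: A_H [zJ] / D0^3 [A^3] = 1e-21 J / 1e-30 m^3 = 1 GPa, so
# S_GPa = (A_H_zJ / (6 pi D0_A^3)) * f(D) and S* = S_GPa / E_GPa.


@dataclass(frozen=True)
class VdwLaw:
    """Hamaker surface-interaction law.

    ``hamaker_zj`` is A_H in zeptojoule (1e-21 J); ``d0`` the equilibrium
    surface separation in A; ``cutoff`` the truncation distance.  The default
    cutoff is far enough out that the residual traction is below 1e-3 of the
    near-well values.
    """

    hamaker_zj: float = 21.0
    d0: float = 3.0
    cutoff: float | None = None
    exponents: tuple[int, int] = (3, 9)

    def __post_init__(self) -> None:
        if self.hamaker_zj <= 0:
            raise ValueError("Hamaker constant must be positive")
        if self.cutoff is None:
            object.__setattr__(self, "cutoff", 14.0 * self.d0)
        if not 0 < self.d0 < self.cutoff:
            raise ValueError("need 0 < d0 < cutoff")
        m, n = self.exponents
        if not (0 < m < n):
            raise ValueError("exponents (m, n) must satisfy 0 < m < n")

    @property
    def prefactor_gpa(self) -> float:
        return self.hamaker_zj / (6.0 * np.pi * self.d0**3)


def vdw_traction(
    distance: np.ndarray | float,
    law: VdwLaw,
    young_modulus_gpa: float = DEFAULT_YOUNG_MODULUS_GPA,
) -> np.ndarray | float:
    """Dimensionless normal traction S/E at surface separation D (A).

    Positive = attraction, negative = repulsion, zero at D0 and beyond the
    cutoff.  Raises for non-positive separations.
    """
    D = np.asarray(distance, dtype=float)
    if np.any(D <= 0):
        raise ValueError("surface separation must be positive")
    m, n = law.exponents
    x = law.d0 / D
    s = law.prefactor_gpa / young_modulus_gpa * (x**m - x**n)
    s = np.where(D >= law.cutoff, 0.0, s)
    return float(s) if np.isscalar(distance) else s


def vdw_energy(
    distance: np.ndarray | float,
    law: VdwLaw,
    young_modulus_gpa: float = DEFAULT_YOUNG_MODULUS_GPA,
) -> np.ndarray | float:
    """Interaction energy per unit area, E*A^2 units; dW/dD = traction.

    Anchored to zero at the cutoff.  For the (3, 9) pair the well depth is
    A_H / (16 pi D0^2) at D = D0.
    """
    D = np.asarray(distance, dtype=float)
    if np.any(D <= 0):
        raise ValueError("surface separation must be positive")
    m, n = law.exponents

    def antideriv(d):
        x = law.d0 / d
        return law.d0 * (x ** (n - 1) / (n - 1) - x ** (m - 1) / (m - 1))

    w = law.prefactor_gpa / young_modulus_gpa * (antideriv(D) - antideriv(law.cutoff))
    w = np.where(D >= law.cutoff, 0.0, w)
    return float(w) if np.isscalar(distance) else w


@dataclass(frozen=True)
class EnergyDistanceTable:
    """Separation (A) vs interaction energy per unit contact area (zJ/A^2)."""

    separations: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.separations, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if s.shape != e.shape or s.ndim != 1:
            raise ValueError("separations and energies must be equal-length 1-D arrays")
        if s.size < 5:
            raise ValueError("energy-distance table needs at least 5 points")
        if not np.all(np.diff(s) > 0):
            raise ValueError("separations must be strictly increasing")
        object.__setattr__(self, "separations", s)
        object.__setattr__(self, "energies", e)


def _energy_zj_per_a2(D: np.ndarray, hamaker_zj: float, d0: float,
                      exponents: tuple[int, int] = (3, 9)) -> np.ndarray:
    """Closed-form well W(D) in physical units (zJ/A^2), zero at infinity."""
    m, n = exponents
    x = d0 / np.asarray(D, dtype=float)
    return hamaker_zj / (6.0 * np.pi * d0**2) * (x ** (n - 1) / (n - 1) - x ** (m - 1) / (m - 1))


def generate_energy_table(
    hamaker_zj: float = 21.0,
    d0: float = 3.0,
    n_points: int = 25,
    d_min: float = 2.2,
    d_max: float = 12.0,
    noise_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> EnergyDistanceTable:
    """Synthetic energy-distance table from a known law (fit oracle input).

    Emulates MD-derived lipid-helix interaction energies; optional
    multiplicative Gaussian noise with relative s.d. ``noise_fraction``.
    """
    D = np.linspace(d_min, d_max, n_points)
    W = _energy_zj_per_a2(D, hamaker_zj, d0)
    if noise_fraction > 0:
        rng = np.random.default_rng(rng)
        W = W * (1.0 + noise_fraction * rng.standard_normal(W.shape))
    return EnergyDistanceTable(D, W)


class HamakerFitError(RuntimeError):
    """Least-squares fit of the interaction law failed; carries diagnostics."""


def fit_hamaker(table: EnergyDistanceTable) -> tuple[VdwLaw, float]:
    """Least-squares fit of the (3, 9) energy well to an energy table.

    Returns ``(law, residual_norm)``.  Initial guesses come from the table
    itself: D0 from the energy minimum, A_H from the well depth.
    """
    D, W = table.separations, table.energies
    imin = int(np.argmin(W))
    d0_guess = float(np.clip(D[imin], D[0] * 1.01, D[-1] * 0.99))
    a_guess = float(max(-W[imin] * 16.0 * np.pi * d0_guess**2, 1e-3))
    if W[imin] >= 0 or imin == len(D) - 1:
        raise HamakerFitError(
            f"table has no interior energy minimum (min {W[imin]:.4g} at index {imin}); "
            "cannot identify an adhesion well"
        )
    try:
        popt, _ = curve_fit(
            _energy_zj_per_a2, D, W, p0=(a_guess, d0_guess),
            bounds=([1e-6, 0.5 * D[0]], [1e4, 2.0 * D[-1]]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise HamakerFitError(f"curve fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(W - _energy_zj_per_a2(D, *popt)))
    scale = float(np.linalg.norm(W))
    if scale > 0 and resid > 0.5 * scale:
        raise HamakerFitError(
            f"fit residual {resid:.3g} exceeds half the data norm {scale:.3g}; "
            "table is inconsistent with a single Hamaker well"
        )
    return VdwLaw(hamaker_zj=float(popt[0]), d0=float(popt[1])), resid


def assemble_contact_tractions(
    gaps: np.ndarray,
    areas: np.ndarray,
    outward_normals: np.ndarray,
    law: VdwLaw,
    young_modulus_gpa: float = DEFAULT_YOUNG_MODULUS_GPA,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slave-node contact forces against the membrane master surface.

    ``gaps`` are closest-point surface separations (A); nodes with
    non-positive or undefined (NaN) gaps get zero traction.  Forces act along
    the outward normals (toward the master) when attractive.  Returns
    ``(slave_forces, master_total)`` with the master reaction equal and
    opposite by construction.
    """
    gaps = np.asarray(gaps, dtype=float)
    areas = np.asarray(areas, dtype=float)
    normals = np.asarray(outward_normals, dtype=float)
    ok = np.isfinite(gaps) & (gaps > 0)
    s = np.zeros_like(gaps)
    if np.any(ok):
        s[ok] = vdw_traction(gaps[ok], law, young_modulus_gpa)
    forces = (s * areas)[:, None] * normals
    return forces, -forces.sum(axis=0)
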