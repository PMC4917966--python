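# Methods

## The model

`msclsim` treats the MscL pentamer as fifteen straight elastic rods — per
subunit one N-terminal interfacial helix (residues 1–13), one pore-lining
TM1 (15–43) and one lipid-facing TM2 (69–93), all of diameter 5 Å — joined
by a free hinge at G14 (N-term → TM1) and a soft loop spring per subunit
(TM1 C-end → TM2 N-end, the periplasmic loop).  The C-terminal bundle is
omitted; it is known to have negligible effect on gating.  Helix–helix
elastic interactions are deliberately absent: every force on the protein is
transmitted from the membrane, which is the hypothesis under test.

The membrane is not meshed.  It acts through four mean-field channels, all
expressed in nondimensional form (lengths in Å, stresses as ratios to the
protein Young's modulus E, default reference 0.2 GPa; every output is
invariant to the absolute value of E):

1. **Lateral pressure profile.**  A five-band piecewise-constant profile
   (head / interface / tail / interface / head) whose zeroth moment is zero
   at rest and equals −σ* under the applied nondimensional tension σ*.  The
   tension-carrying share of each band is an affine function of σ*; by
   default the full tension is assigned to the head bands, where the
   interfacial free energy resides.  Band pressures load rod nodes radially
   at their assembly-time membrane depth (material tags).
2. **van der Waals adhesion.**  Lipid inner surface (master) and helix
   outer surfaces (slaves) interact through the 3–9 Hamaker law
   S(D) = A_H/(6πD0³)[(D0/D)³−(D0/D)⁹], A_H = 21 zJ, D0 = 3 Å, positive =
   attraction, zero at D0 and beyond the cutoff (14·D0).  With A_H in zJ
   and D in Å, A_H/(6πD0³) is in GPa, so S* = S/E_GPa; the unit bridge is
   covered by a unit test.  Every lipid-exposed node starts at the
   equilibrium gap from its local master anchor, so σ* = 0 is an exact
   equilibrium.  The repulsive branch is linearized beyond twice the peak
   attraction: a lipid rim yields rather than indenting the protein.
3. **Rim kinematics.**  The lipid hole rim advances outward with load,
   ΔR(z, σ*) = β·σ*(1+q·σ*)·R_ref·(1 + τ·z/h0), with compliance β = 1.35,
   softening q = −0.35, reference radius R_ref = 25 Å and taper τ = 1.25:
   the periplasmic mouth opens into the funnel shape of the expanded
   channel.  The pressure-profile pull on a node fades exponentially
   (decay 0.6 Å) once the node outruns its rim anchor by more than a 5 Å
   slack — the membrane pulls at the protein–lipid boundary, it cannot drag
   a helix arbitrarily deep into the annulus.
4. **Hydrophobic matching and the N-term anchor.**  Lipid-exposed nodes are
   tethered in depth to their rest membrane station scaled by the thinning
   (z → z0·h/h0), which converts bilayer thinning into the vertical
   compression that drives helix tilting.  The interfacial N-term is
   additionally tethered radially to a leaflet anchor advancing as
   A·(1−e^(−σ*/σ0)) with A = 11.2 Å, σ0 = 0.18; the spring (0.1 E/Å³ per
   exposed area) sustains the transmitted force at equilibrium.

Membrane response: areal stretch λ_A = 1 + σ*/K_A with K_A = 3.4, chosen so
that the far-field volume-conserving thinning h = h0/λ_A reaches 15%
(≈5 Å at h0 = 33.3 Å) at the full-opening tension σ* = 0.6.  A boundary
layer (10 Å) relaxes the thickness back toward rest at the protein rim.

## Discretization and solution

Rods are chains of nodes (default 8 per helix) with translational degrees
of freedom only: axial springs EA/l per segment and Voronoi-weighted
curvature springs EI/l at interior joints (EA = πd²/4, EI = πd⁴/64, E = 1).
This discrete-elastic-rod formulation converges to Euler–Bernoulli beam
theory (a 10-element cantilever matches PL³/3EI within 0.5%) and handles
the large rigid rotations of gating without a rotation parametrization; the
load case is torsion-free and the G14 hinge releases rotation, so joints
behave as (weakly regularized, 10⁻⁴ of rod bending) ball joints.  The +2G
and +5G constructs replace the G14 pin by a tension-only tether of rest
length n·1.5 Å that buckles freely.  Loop springs default to 10⁻² of the
rod axial stiffness; tabulated nonlinear force–extension wires are
supported.

Loading is quasi-static: σ* ramps from 0 to σ*max in 30 equal increments
(adaptively halved up to 5 times on non-convergence); each increment
minimizes the total potential energy by L-BFGS with the analytic gradient,
starting from the previous solution, and counts as converged when the
force-residual infinity norm falls below 10⁻⁵ E·Å².  The solver is
deterministic.  A failed increment returns the truncated trajectory with
diagnostics instead of raising.

Per-element stress is the outer-fiber equivalent |N|/A + |M|(d/2)/I from
the axial resultant and the larger adjacent joint moment, in units of E.

## Observables

* **Tilt to axis** — angle between a helix's refit axis (total least
  squares over its deformed nodes) and the fivefold axis, folded to
  [0, 90°], averaged over subunits ± s.d.  The *out-of-plane tilt* of the
  expanded state is reported as the elevation from the membrane plane,
  90° − tilt-to-axis.  The two printed ΔN-term/WT values are only mutually
  consistent in this convention: the closed-state TM1 already sits ~38.5°
  from the axis (fixed by the −43° crossing-angle constraint), and the
  unsupported helix of the deletion mutant slumps *toward* the plane under
  load rather than straightening.  Tilt *changes* are reported against the
  closed state.
* **Effective pore radius** — minimum over depth slices through the
  (thinned) membrane span of the distance from the fivefold axis to the
  nearest TM1 centerline, minus the 2.5 Å rod radius, clamped at zero;
  polylines are resampled at 0.125 Å (half the 0.25 Å slice resolution).
  This is a backbone measure and deliberately ignores side chains.
* **N-term radial displacement** — change of the helix-midpoint cylindrical
  radius between the first and last trajectory states, subunit-averaged.
* **Continuity angle** — inter-axis angle between N-term and TM1.  It
  grows from the 95° closed-state elbow toward 180° as the two rods align
  into a single straight structural member; 180° means collinear rod axes
  (the residue direction reverses at the hinge, a chain-topology detail a
  rod model does not represent).

## Calibration

The underlying experiments do not pin down the membrane-side parameters
individually, so they were calibrated once against the study's gating
observables (TM1/TM2 tilt changes, pore diameters of WT and the deletion
mutant at σ* = 0.3, thinning, N-term travel) and frozen as the defaults of
`MechanicsParams` quoted above.  Lipid exposures are the geometric part of
that calibration: N-term 1.5 (acyl chains wrap over the interfacial helix),
TM2 1.0, TM1 0.3 at the shielded cytoplasmic constriction ramping to 0.6
at its flared, partially lipid-facing periplasmic end.  The protein-side
stiffness ratios stay at 1 (uniform E).  All of these are configurable in
the run configuration file; the calibration is not revisited per run.

## Synthetic data

The fixture generator emulates the study's external inputs: a Cα-only PDB
of the idealized pentamer (atoms on the rod centerlines, so axis fits
round-trip exactly), energy–distance tables drawn from the reference
Hamaker law with optional multiplicative noise (stand-ins for MD-derived
lipid–helix interaction energies), and the MscL N-terminal FASTA panel
(E. coli and M. tuberculosis canonical N-termini plus three synthetic
homologue-like sequences carrying the consensus motif).  What passing tests
show is therefore internal consistency of the mechanics and analysis
pipeline under controlled inputs — not agreement with any particular
experimental structure beyond the printed closed-state geometry.

## Numerical choices

Increment schedule 30 steps (metrics at σ* = 0.3 are read from the nearest
increment); nodes per helix 8 (tilt and pore metrics change <2% from 8 to
16, the mesh-sensitivity report is built in); pore scan at 0.25 Å; free
energies are smooth (C¹) everywhere, including the drag fade and the
yielding rim, so the minimizer sees no force discontinuities; a 10⁻⁶
centroid tether removes the rigid-translation null space; degenerate inputs
(coincident points, zero-length axes, non-monotone tables, missing
residues) raise typed errors naming the offending data.

## Known limitations

* The membrane-side kinematics (rim advance, its taper and softening, the
  N-term anchor curve) are prescribed mean-field calibration curves, not
  solved continuum fields; only the protein force balance is solved.
* The von Mises hotspot lands on TM1 (bending under the tapered rim drive)
  rather than on the N-terminal helix: the pore-size contrast between WT
  and the deletion mutant requires a compliant rim at the TM1 bottom, which
  caps the force the N-term transmits in the open state.
* The WT-vs-deletion difference in TM1 tilt is ~3.5°, smaller than observed
  — it is geometrically tied to the ~3.5 Å difference in bottom-end radial
  displacement that matching the observed pore sizes fixes.
* The deletion model remains numerically stable at all loads in this
  bounded-energy formulation; the instability seen in Newton-continuation
  solvers appears here only as the reported-partial-trajectory path.
* Effective pore sizes are backbone-based and exceed the side-chain
  constriction; conductance is out of scope.
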