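# msclsim

Continuum elastic-rod simulation of gating in MscL, the bacterial
mechanosensitive channel of large conductance, together with the sequence
analyses that frame the role of its amphipathic N-terminal helix.

MscL is a homopentamer that opens a ~3 nS pore in response to membrane
tension alone.  Each subunit contributes a pore-lining TM1 helix, a
lipid-facing TM2 helix, and a short amphipathic N-terminal helix that lies
in the plane of the cytoplasmic membrane interface and is coupled to TM1
through the flexible glycine G14.  `msclsim` asks a mechanical question at
the continuum level: if the helices are nothing but elastic rods, and the
only forces acting on them come from a tension-loaded bilayer — a
depth-resolved lateral pressure profile and a Hamaker-type van der Waals
adhesion between lipid and helix surfaces,

    S(D) = A_H / (6 π D0³) · [ (D0/D)³ − (D0/D)⁹ ],

with A_H ≈ 21 zJ — does the channel open the way the full structure does,
and does it stop opening when the N-terminal helix is deleted or its linker
extended by glycines (+2G, +5G)?

The package provides:

* **geometry** — helix-axis fitting (total least squares over Cα
  coordinates), signed crossing angles and inter-axis angles, closest
  approaches, and a deterministic idealized C5 pentamer builder that
  realizes the published closed-state geometry (adjacent TM1–TM1 crossing
  −43°, TM1–TM2 packing +10°/169°, TM2–TM2 separation 20 Å, N-term/TM1 link
  95°); structures can also be read from PDB files.
* **membrane** — five-band lateral pressure profile whose zeroth moment
  vanishes at rest and carries the applied nondimensional tension σ* under
  load; volume-conserving thinning with a rim boundary layer.
* **vdw** — the 3–9 surface-traction law, its energy, and Hamaker-constant
  fitting to (synthetic, MD-like) energy–distance tables.
* **solver** — a quasi-static discrete-elastic-rod solver (axial plus
  curvature springs, free hinges at G14, loop springs, incremental energy
  minimization) with per-element von Mises output, nondimensionalized by
  the protein Young's modulus E.
* **metrics** — helix tilts versus the fivefold axis, backbone effective
  pore radius, N-term radial travel, N-term/TM1 continuity angle, and
  WT / ΔN-term / +nG comparison experiments.
* **sequence** — normalized hydrophobic moments (μH), helical wheels,
  charge statistics, and PROSITE-style scanning for the conserved
  `F-[K,R]-x-F-[A,I,L]-x-[K,R]-G` motif of MscL N-termini.

## Worked example

```python
>>> from msclsim import build_idealized, measure_model
>>> from msclsim.solver import SolverConfig, assemble_system, solve_quasistatic
>>> from msclsim.metrics import gating_report
>>> model = build_idealized()                      # closed-state WT pentamer
>>> {k: round(v, 1) for k, v in measure_model(model).items()}
{'cross_tm1_tm1_adj': -43.0, 'angle_tm1_tm2_same': 135.0,
 'angle_tm1_tm2_adj': 169.0, 'cross_tm1_tm2_adj': 11.0,
 'gap_tm2_tm2_adj': 20.0, 'tm1_tilt_to_axis': 38.5,
 'tm2_tilt_to_axis': 30.0, 'angle_nterm_tm1': 95.0}
>>> system = assemble_system(model, SolverConfig(sigma_max=0.6))
>>> report = gating_report(system, solve_quasistatic(system))
>>> final = report.final
>>> round(final.tm1_tilt_change_deg, 1), round(final.thinning_pct, 1)
(21.1, 15.0)
>>> round(final.nterm_radial_disp_A, 1), round(final.pore_diameter_A, 1)
(10.9, 27.2)
```

Reading: ramping the nondimensional membrane tension to σ* = 0.6 tilts TM1
by 21° toward the membrane plane, thins the bilayer by 15% (≈5 Å), moves
the N-terminal helix ~11 Å radially outward, and expands the backbone
effective pore to ~27 Å diameter.  Deleting the N-terminal helices
(`build_idealized(has_nterm=False)`) leaves the pore roughly a third
narrower at matched tension (16.3 Å vs 25.4 Å diameter at σ* = 0.3) — the
N-term is the force-transmitting element.

The same runs are available from the shell:

```sh
msclsim geometry --json
msclsim simulate --out-dir runs/wt
msclsim compare DELTA_NTERM --sigma-max 0.3
msclsim amphipathy fixtures/mscl_nterm.fasta
msclsim mesh-check --levels 4,8,16
```

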