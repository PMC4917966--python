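"""Deterministic fixture generation: structures, energy tables, sequences.

These stand in for the external inputs of a full study — a homology-model
structure, MD-derived lipid-helix interaction energies, and the alignment
panel of MscL N-terminal sequences — so every analysis in the package can
run self-contained.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import IdealizedParams, build_idealized, write_ca_pdb
from .vdw import generate_energy_table

__all__ = ["MSCL_NTERM_SEQUENCES", "generate_fixture"]

#: N-terminal sequences for the amphipathic-helix panel.  The E. coli and
#: M. tuberculosis entries are the canonical UniProt N-termini; the *_SYN
#: entries are synthetic homologue-like sequences constructed to carry the
#: conserved F-[K,R]-x-F-[A,I,L]-x-[K,R]-G motif at homologous positions.
MSCL_NTERM_SEQUENCES: dict[str, str] = {
    "EcMscL": "MSIIKEFREFAMRGNVVDLA",
    "MtMscL": "MLKGFKEFLARGNIVDLAVA",
    "SYN_A": "MGLIKEFKAFALRGNVIDMA",
    "SYN_B": "MSFLKGFKEFIMRGNVVELA",
    "SYN_C": "MNVIREFKDFALRGNLVDMA",
}


def generate_fixture(
    kind: str,
    out_dir: str | Path,
    seed: int = 0,
    params: IdealizedParams | None = None,
    noise_fraction: float = 0.0,
    on_axis: bool = True,
) -> Path:
    """Write one fixture file; byte-identical for identical seeds.

    Kinds: ``idealized_pdb`` (C-alpha pentamer realizing the printed closed-
    state geometry), ``energy_table`` (lipid-helix interaction energies from
    the reference Hamaker law, optionally noisy), ``sequences`` (the MscL
    N-terminal FASTA panel).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "idealized_pdb":
        model = build_idealized(params)
        return write_ca_pdb(model, out_dir / "idealized_mscl.pdb", on_axis=on_axis)
    if kind == "energy_table":
        table = generate_energy_table(noise_fraction=noise_fraction, rng=seed)
        path = out_dir / "energy_table.csv"
        lines = ["separation_A,energy_zj_per_A2"]
        lines += [f"{d:.6f},{e:.8f}" for d, e in zip(table.separations, table.energies)]
        path.write_text("\n".join(lines) + "\n")
        return path
    if kind == "sequences":
        path = out_dir / "mscl_nterm.fasta"
        lines = []
        for name, seq in MSCL_NTERM_SEQUENCES.items():
            lines.append(f">{name} MscL N-terminal helix region")
            lines.append(seq)
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unknown fixture kind {kind!r}")


def read_energy_table_csv(path: str | Path):
    """Load a 2-column energy-distance CSV back into an EnergyDistanceTable."""
    from .vdw import EnergyDistanceTable

    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return EnergyDistanceTable(data[:, 0], data[:, 1])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning {identifier: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
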