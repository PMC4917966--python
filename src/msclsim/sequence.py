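"""Sequence-level analysis of interfacial amphipathic helices.

Amphipathic helices such as the MscL N-terminal helix segregate hydrophobic
and polar residues onto opposite faces of the helical cylinder.  This module
quantifies that segregation (normalized hydrophobic moment), summarizes the
charge character that marks interfacial helices, lays residues out on a
helical wheel, and scans sequences for PROSITE-style consensus motifs like
the conserved ``F-[K,R]-x-F-[A,I,L]-x-[K,R]-G`` of bacterial MscL N-termini.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeptideSequence",
    "HydrophobicityScale",
    "SequenceMotif",
    "SCALES",
    "hydrophobic_moment",
    "max_window_moment",
    "charge_stats",
    "wheel_coordinates",
    "motif_scan",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Fauchere & Pliska (1983) octanol/water transfer free energies, kcal/mol.
_FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

# Eisenberg consensus scale (1984).
_EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Kyte & Doolittle (1982) hydropathy.
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Named per-residue hydrophobicity table; unknown residue X scores 0."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        if aa == "X":
            return 0.0
        try:
            return self.values[aa]
        except KeyError:
            raise KeyError(f"unknown residue {aa!r} in scale {self.name!r}") from None


SCALES: dict[str, HydrophobicityScale] = {
    "fauchere-pliska": HydrophobicityScale("fauchere-pliska", _FAUCHERE_PLISKA),
    "eisenberg": HydrophobicityScale("eisenberg", _EISENBERG),
    "kyte-doolittle": HydrophobicityScale("kyte-doolittle", _KYTE_DOOLITTLE),
}


@dataclass(frozen=True)
class PeptideSequence:
    """One-letter protein sequence with 1-based numbering.

    ``offset`` is the residue number of the first letter (default 1), so a
    construct beginning at residue 15 can keep its native numbering.
    """

    identifier: str
    residues: str
    offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def window(self, start: int, end: int) -> str:
        """Inclusive 1-based slice in the sequence's own numbering."""
        i, j = start - self.offset, end - self.offset + 1
        if i < 0 or j > len(self.residues) or i >= j:
            raise IndexError(f"window {start}..{end} outside {self.identifier!r}")
        return self.residues[i:j]


def _resolve_scale(scale: str | HydrophobicityScale) -> HydrophobicityScale:
    if isinstance(scale, HydrophobicityScale):
        return scale
    try:
        return SCALES[scale]
    except KeyError:
        raise KeyError(f"unknown scale {scale!r}; registered: {sorted(SCALES)}") from None


def hydrophobic_moment(
    window: str,
    scale: str | HydrophobicityScale = "fauchere-pliska",
    twist_deg: float = 100.0,
) -> tuple[float, float]:
    """Normalized helical hydrophobic moment of a residue window.

    mu_H = | sum_n H_n (cos n*delta, sin n*delta) | / N with delta the helix
    twist per residue (100 deg for an ideal alpha-helix).  Returns
    ``(mu_H, azimuth_deg)`` where the azimuth is the direction of the
    hydrophobic face on the wheel, in [0, 360).
    """
    if len(window) < 3:
        raise ValueError("hydrophobic moment needs a window of >= 3 residues")
    sc = _resolve_scale(scale)
    delta = math.radians(twist_deg)
    h = np.array([sc[aa] for aa in window])
    n = np.arange(len(window))
    vx = float(np.sum(h * np.cos(n * delta)))
    vy = float(np.sum(h * np.sin(n * delta)))
    mu = math.hypot(vx, vy) / len(window)
    azimuth = math.degrees(math.atan2(vy, vx)) % 360.0
    return mu, azimuth


def max_window_moment(
    seq: PeptideSequence | str,
    window_length: int = 11,
    scale: str | HydrophobicityScale = "fauchere-pliska",
    twist_deg: float = 100.0,
) -> tuple[float, int]:
    """Maximum mu_H over all windows of ``window_length``; returns (mu_H, start).

    ``start`` is 1-based in the sequence's own numbering.  This is the default
    reduction used to call a declared helix "amphipathic" (threshold 0.45 in
    the interfacial-helix literature).
    """
    residues = seq.residues if isinstance(seq, PeptideSequence) else seq
    offset = seq.offset if isinstance(seq, PeptideSequence) else 1
    if len(residues) < window_length:
        raise ValueError(f"sequence shorter than window ({len(residues)} < {window_length})")
    best, best_start = -1.0, offset
    for i in range(len(residues) - window_length + 1):
        mu, _ = hydrophobic_moment(residues[i : i + window_length], scale, twist_deg)
        if mu > best:
            best, best_start = mu, i + offset
    return best, best_start


def charge_stats(seq: PeptideSequence | str) -> dict[str, float]:
    """Net charge and charged-residue fraction.

    D/E count −1, K/R +1; histidine is treated as neutral and termini are not
    ionized, the usual helical-wheel convention.  The charged fraction counts
    D, E, K, R over the full length, in percent.
    """
    residues = seq.residues if isinstance(seq, PeptideSequence) else seq
    pos = sum(residues.count(aa) for aa in "KR")
    neg = sum(residues.count(aa) for aa in "DE")
    n = len(residues)
    return {
        "net_charge": pos - neg,
        "charged_fraction_pct": 100.0 * (pos + neg) / n if n else 0.0,
    }


def wheel_coordinates(window: str, twist_deg: float = 100.0) -> list[dict[str, float | str]]:
    """Helical-wheel layout: residue n at azimuth n*twist (mod 360), radius 1."""
    if len(window) < 1:
        raise ValueError("empty window")
    out = []
    for n, aa in enumerate(window):
        out.append(
            {
                "index": n,
                "residue": aa,
                "azimuth_deg": (n * twist_deg) % 360.0,
                "radius": 1.0,
            }
        )
    return out


class MotifParseError(ValueError):
    """Malformed PROSITE-style pattern; carries the offending element index."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (element {position})")
        self.position = position


@dataclass
class SequenceMotif:
    """Compiled PROSITE-style pattern.

    Supported grammar (elements joined by ``-``): a literal residue, ``x``
    for any residue, ``[AB...]`` or ``[A,B,...]`` for alternatives, ``{AB}``
    for exclusions, and an optional ``(n)`` repeat on any element.
    """

    pattern: str
    classes: list[frozenset[str]] = field(init=False, repr=False)

    _ELEM = re.compile(
        r"^(?:(?P<any>x)|(?P<lit>[A-Z])|\[(?P<alt>[A-Z,]+)\]|\{(?P<exc>[A-Z,]+)\})"
        r"(?:\((?P<rep>\d+)\))?$"
    )

    def __post_init__(self) -> None:
        self.classes = []
        elements = self.pattern.strip().strip(".").split("-")
        for k, elem in enumerate(elements, start=1):
            m = self._ELEM.match(elem.strip())
            if m is None:
                raise MotifParseError(f"cannot parse element {elem!r}", k)
            if m.group("any"):
                cls = frozenset(STANDARD_AA)
            elif m.group("lit"):
                cls = frozenset(m.group("lit"))
            elif m.group("alt"):
                cls = frozenset(m.group("alt").replace(",", ""))
            else:
                cls = frozenset(STANDARD_AA) - frozenset(m.group("exc").replace(",", ""))
            if not cls <= STANDARD_AA or not cls:
                raise MotifParseError(f"invalid residue class in {elem!r}", k)
            rep = int(m.group("rep") or 1)
            if rep < 1:
                raise MotifParseError(f"repeat count must be >= 1 in {elem!r}", k)
            self.classes.extend([cls] * rep)

    def __len__(self) -> int:
        return len(self.classes)

    def __str__(self) -> str:
        return self.pattern

    def matches_at(self, residues: str, i: int) -> bool:
        """Check a match with window start at 0-based index ``i``."""
        if i + len(self.classes) > len(residues):
            return False
        return all(residues[i + k] in cls for k, cls in enumerate(self.classes))


def motif_scan(
    seq: PeptideSequence | str, motif: SequenceMotif | str
) -> list[tuple[int, str]]:
    """All (possibly overlapping) motif matches as (1-based start, span).

    Start positions respect the sequence's numbering offset.
    """
    if isinstance(motif, str):
        motif = SequenceMotif(motif)
    residues = seq.residues if isinstance(seq, PeptideSequence) else seq
    offset = seq.offset if isinstance(seq, PeptideSequence) else 1
    hits = []
    for i in range(len(residues) - len(motif) + 1):
        if motif.matches_at(residues, i):
            hits.append((i + offset, residues[i : i + len(motif)]))
    return hits
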