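"""Physicochemical and cysteine-framework annotation of candidate peptides.

Two net-charge models are provided. The headline integer model counts
Lys/Arg as +1 and Asp/Glu as −1 at pH 7, treats His as neutral, and lets
the termini cancel (+1 N-terminus, −1 C-terminus, reported separately);
this is the convention that reproduces the published −1/−5 values for the
two *Laurentiella* defensins. A continuous Henderson–Hasselbalch model is
available as a refinement.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .motif_profile import gamma_core_c_terminal_most

__all__ = [
    "PeptideAnnotation",
    "CysteineFramework",
    "net_charge_integer",
    "net_charge_hh",
    "cysteine_framework",
    "annotate",
    "PKA_SETS",
]

_POSITIVE = set("KR")
_NEGATIVE = set("DE")

# Side-chain and terminal pKa values. EMBOSS: the defaults of the EMBOSS
# charge/iep tools; Lehninger: the common textbook set.
PKA_SETS: dict[str, dict[str, float]] = {
    "EMBOSS": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "Lehninger": {
        "Nterm": 9.69, "Cterm": 2.34,
        "K": 10.53, "R": 12.48, "H": 6.0,
        "D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07,
    },
}


def net_charge_integer(peptide: str, include_termini: bool = False) -> int:
    """Integer net charge at pH 7: +1 per K/R, −1 per D/E, His and X neutral.

    The termini contribute +1 and −1 (net 0); set ``include_termini`` to add
    them explicitly (a no-op on the total, kept for transparency).
    """
    charge = sum((c in _POSITIVE) - (c in _NEGATIVE) for c in peptide)
    if include_termini:
        charge += 1 - 1
    return charge


def net_charge_hh(peptide: str, pH: float = 7.0, pKa_set: str = "EMBOSS") -> float:
    """Henderson–Hasselbalch fractional net charge over D,E,C,Y,H,K,R and termini."""
    if not 0 < pH < 14:
        raise ValueError(f"pH {pH} outside (0, 14)")
    try:
        pka = PKA_SETS[pKa_set]
    except KeyError:
        raise ValueError(
            f"unknown pKa set {pKa_set!r}; available: {sorted(PKA_SETS)}"
        ) from None

    def basic(pk: float) -> float:
        return 1.0 / (1.0 + 10 ** (pH - pk))

    def acidic(pk: float) -> float:
        return -1.0 / (1.0 + 10 ** (pk - pH))

    charge = basic(pka["Nterm"]) + acidic(pka["Cterm"])
    for c in peptide:
        if c in "KRH":
            charge += basic(pka[c])
        elif c in "DECY":
            charge += acidic(pka[c])
    return charge


@dataclass(frozen=True)
class CysteineFramework:
    cys_count: int
    cys_positions: tuple[int, ...]
    bridge_pattern_label: Optional[str]
    tarr_array_label: Optional[str]


#: Sequence-order disulfide connectivity assumed for the CS-αβ scaffold.
CSAB_BRIDGE_LABEL = "1-4,2-5,3-6"
#: The same framework expressed in the ten-cysteine reference array used to
#: classify CS-αβ superfamily members (insect-defensin pattern). Emitted as
#: an opaque classification label, not recomputed from a reference alignment.
TARR_INSECT_DEFENSIN_LABEL = "C2-C6, C3-C8, C4-C9"


def cysteine_framework(peptide: str) -> CysteineFramework:
    """Count and locate cysteines; label the framework when exactly six.

    The 1-4/2-5/3-6 label is a sequence-order assignment under the CS-αβ
    assumption (two bridges tying the helix to the C-terminal strand, one
    tying the N-terminus to the first strand); geometry-derived bridges
    live in :mod:`csabminer.structure_tools`.
    """
    positions = tuple(i + 1 for i, c in enumerate(peptide) if c == "C")
    if len(positions) == 6:
        return CysteineFramework(6, positions, CSAB_BRIDGE_LABEL, TARR_INSECT_DEFENSIN_LABEL)
    return CysteineFramework(len(positions), positions, None, None)


@dataclass(frozen=True)
class PeptideAnnotation:
    length_aa: int
    net_charge_integer: int
    net_charge_hh: float
    cys_count: int
    cys_positions: tuple[int, ...]
    bridge_pattern_label: Optional[str]
    gamma_core_span: Optional[tuple[int, int]]


def annotate(peptide: str, pH: float = 7.0, pKa_set: str = "EMBOSS") -> PeptideAnnotation:
    """Full physicochemical annotation of one (mature) peptide."""
    fw = cysteine_framework(peptide)
    gc = gamma_core_c_terminal_most(peptide)
    return PeptideAnnotation(
        length_aa=len(peptide),
        net_charge_integer=net_charge_integer(peptide),
        net_charge_hh=net_charge_hh(peptide, pH=pH, pKa_set=pKa_set),
        cys_count=fw.cys_count,
        cys_positions=fw.cys_positions,
        bridge_pattern_label=fw.bridge_pattern_label,
        gamma_core_span=(gc.start, gc.end) if gc else None,
    )
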