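"""Bundled reference peptides and the canonical CS-αβ cysteine profile.

The two *Laurentiella* sp. defensin precursors (LsAMP-1, LsAMP-2) ship with
the package as plantable payloads for the synthetic-genome generator and as
characterization fixtures. Signal-peptide boundaries follow the published
precursor annotation (25 and 26 residues respectively).
"""
from __future__ import annotations

from importlib import resources

__all__ = [
    "LSAMP1_PRECURSOR",
    "LSAMP2_PRECURSOR",
    "LSAMP1_MATURE",
    "LSAMP2_MATURE",
    "SIGNAL_ENDS",
    "CSAB_PROFILE_TEXT",
    "GAMMA_CORE_PATTERN",
    "lsamp_precursors",
    "lsamp_matures",
    "csab_profile_text",
]

LSAMP1_PRECURSOR = (
    "MVFSKSFLLTLYFFIATILLNLVQA"
    "DVDVGSCFVFLPDYRSDCNGYCQQRGYKGGHCGSIFNVKCWCET"
)
LSAMP2_PRECURSOR = (
    "MSINSQIRVLVLFVFLVLTYINQVSA"
    "DVLIGSCVWGAVDYKSDCSGYCESRGYSGGHCGSFGNVDCWCNVDE"
)

#: 1-based index of the last signal-peptide residue of each precursor.
SIGNAL_ENDS = {"LsAMP-1": 25, "LsAMP-2": 26}

LSAMP1_MATURE = LSAMP1_PRECURSOR[SIGNAL_ENDS["LsAMP-1"]:]
LSAMP2_MATURE = LSAMP2_PRECURSOR[SIGNAL_ENDS["LsAMP-2"]:]

#: Conserved CS-αβ defensin cysteine-distribution profile (fuzzy pattern,
#: PROSITE-like bounded gaps). Note the Unicode minus in the subscripts,
#: accepted verbatim by the profile compiler.
CSAB_PROFILE_TEXT = "CX2−18CX3CX2−10[GAPSIDERYW]X1CX4−17CXC"

#: γ-core signature: Gly-X-Cys-X(3..9)-Cys.
GAMMA_CORE_PATTERN = "GXCX3-9C"


def lsamp_precursors() -> dict[str, str]:
    """Return the two bundled defensin precursors as an ordered id→sequence map."""
    return {"LsAMP-1": LSAMP1_PRECURSOR, "LsAMP-2": LSAMP2_PRECURSOR}


def lsamp_matures() -> dict[str, str]:
    """Return the mature (signal-cleaved) peptides."""
    return {"LsAMP-1": LSAMP1_MATURE, "LsAMP-2": LSAMP2_MATURE}


def csab_profile_text() -> str:
    """Read the shipped profile pattern file (identical to CSAB_PROFILE_TEXT)."""
    ref = resources.files("csabminer").joinpath("data/csab_profile.txt")
    return ref.read_text(encoding="utf-8").strip()


def precursor_fasta_path():
    """Path-like resource for the bundled precursor FASTA."""
    return resources.files("csabminer").joinpath("data/lsamp_precursors.fasta")
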