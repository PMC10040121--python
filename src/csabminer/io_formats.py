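"""FASTA readers/writers and the candidate output table.

Pure plumbing: nothing in here knows about defensins beyond the column
layout of the candidate table. Nucleotide input is normalized aggressively
(lowercase → uppercase, U → T, anything outside {A,C,G,T,N} → N with a
logged warning) because draft assemblies routinely carry IUPAC ambiguity
codes that the mining stages cannot use.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

PathType = Union[str, PathLike]

_NT_KEEP = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass
class GenomeAssembly:
    """Ordered scaffold-id → uppercase nucleotide string ({A,C,G,T,N})."""

    scaffolds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            if not sid:
                raise ValueError("empty scaffold id")
            if not seq:
                raise ValueError(f"scaffold {sid!r} has empty sequence")
            bad = set(seq) - _NT_KEEP
            if bad:
                raise ValueError(
                    f"scaffold {sid!r} contains non-normalized characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.scaffolds)

    def total_bp(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())


@dataclass
class PeptideSet:
    """Ordered id → amino-acid string (20 standard letters + X)."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, seq in self.records.items():
            if not pid:
                raise ValueError("empty peptide id")
            if not seq:
                raise ValueError(f"peptide {pid!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.records)


def _normalize_nt(seq: str, record_id: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _NT_KEEP
    if bad:
        logger.warning(
            "scaffold %s: %d non-ACGTN character kinds (%s) mapped to N",
            record_id,
            len(bad),
            "".join(sorted(bad)),
        )
        seq = "".join(c if c in _NT_KEEP else "N" for c in seq)
    return seq


def read_fasta_nucleotide(path: PathType) -> GenomeAssembly:
    """Read a nucleotide FASTA into a :class:`GenomeAssembly`.

    Lowercase is uppercased, U becomes T, and any other non-ACGTN character
    becomes N (with a warning). Record order is preserved; duplicate ids and
    empty files are format errors.
    """
    scaffolds: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise FastaFormatError(f"duplicate scaffold id {rec.id!r}")
        seq = _normalize_nt(str(rec.seq), rec.id)
        if not seq:
            raise FastaFormatError(f"scaffold {rec.id!r} has empty sequence")
        scaffolds[rec.id] = seq
    if not scaffolds:
        raise FastaFormatError(f"no FASTA records in {path}")
    return GenomeAssembly(scaffolds)


def read_fasta_protein(path: PathType) -> PeptideSet:
    """Read a protein FASTA into a :class:`PeptideSet`.

    Sequences are uppercased; one terminal '*' is stripped; an internal '*'
    is a format error reported with its 1-based position.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaFormatError(f"duplicate peptide id {rec.id!r}")
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise FastaFormatError(
                f"peptide {rec.id!r}: internal stop '*' at position {seq.index('*') + 1}"
            )
        if not seq:
            raise FastaFormatError(f"peptide {rec.id!r} has empty sequence")
        records[rec.id] = seq
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return PeptideSet(records)


def write_fasta_protein(peptides: PeptideSet, path: PathType, width: int = 60) -> None:
    """Write a PeptideSet as wrapped FASTA (round-trips through the reader)."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid, seq in peptides.records.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def format_position(start: int, end: int) -> str:
    """Render coordinates in the published '[start - end]' style.

    Minus-strand features carry start > end in forward coordinates, so the
    rendering is simply the two numbers in record order.
    """
    return f"[{start} - {end}]"


#: Fixed candidate-table column order (mirrors the published summary table).
CANDIDATE_TABLE_HEADER = (
    "defensin_id",
    "host",
    "scaffold",
    "position",
    "strand",
    "precursor_seq",
    "mature_seq",
    "best_hit",
    "best_hit_pct_id",
    "amp_scores",
    "stages_passed",
)


def write_candidates_table(candidates: Iterable, path: PathType, host: str = "") -> None:
    """Write screening candidates as a TSV with the fixed header.

    ``candidates`` are ``screen_pipeline.PeptideCandidate`` objects (duck-typed:
    any object with ``orf``, ``precursor_seq``, ``mature_seq``, ``verdicts``,
    ``best_hit``/``best_hit_pct_id``/``amp_scores`` attributes or defaults).
    An empty iterable produces a header-only file.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CANDIDATE_TABLE_HEADER) + "\n")
        for i, cand in enumerate(candidates, 1):
            orf = cand.orf
            row = (
                getattr(cand, "candidate_id", f"candidate_{i}"),
                host,
                orf.scaffold_id,
                format_position(orf.start, orf.end),
                orf.strand,
                cand.precursor_seq,
                cand.mature_seq or "",
                str(getattr(cand, "best_hit", "") or ""),
                str(getattr(cand, "best_hit_pct_id", "") or ""),
                ";".join(
                    f"{v.stage_name}={v.detail}" for v in cand.verdicts
                    if v.stage_name.startswith("amp")
                ),
                ",".join(v.stage_name for v in cand.verdicts if v.passed),
            )
            fh.write("\t".join(row) + "\n")
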