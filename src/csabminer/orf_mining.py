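"""Six-frame ORF extraction under selectable genetic codes.

The first mining stage. An ORF is a maximal stop-free codon run bounded by
stop codons or by the scaffold ends (stop-to-stop, as `getorf` reports
them); with ``require_met`` the run is trimmed to its first Met and dropped
if it has none. Ciliate nuclear genomes reassign TAA/TAG to glutamine
(NCBI translation table 6), which is what makes standard-code ORF calling
truncate their genes — the motivating failure mode for this module.

Coordinates are 1-based inclusive on the forward strand; minus-strand ORFs
are reported with start > end (the position of the first codon base is
always ``start``), matching the published "[977 - 771]" convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio.Data import CodonTable

from .io_formats import GenomeAssembly

logger = logging.getLogger(__name__)

_BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP = "*"


class TranslationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon → amino-acid/STOP map with its NCBI table id."""

    table_id: int
    codon_map: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise ValueError(f"codon map must have 64 entries, got {len(self.codon_map)}")
        for codon, aa in self.codon_map.items():
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise ValueError(f"bad codon {codon!r}")
            if aa != STOP and (len(aa) != 1 or not aa.isalpha()):
                raise ValueError(f"bad amino acid {aa!r} for codon {codon!r}")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_map.items() if aa == STOP)

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        """Build from the NCBI unambiguous DNA codon tables (1 = standard,
        6 = ciliate/dasycladacean nuclear: TAA→Q, TAG→Q)."""
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        cmap = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            cmap[stop] = STOP
        return cls(table_id=table_id, codon_map=cmap)

    @classmethod
    def from_codon_map(cls, table_id: int, codon_map: Mapping[str, str]) -> "GeneticCode":
        return cls(table_id=table_id, codon_map=dict(codon_map))


STANDARD_CODE = GeneticCode.from_ncbi(1)
CILIATE_CODE = GeneticCode.from_ncbi(6)


@dataclass(frozen=True)
class OrfRecord:
    """A called ORF (Met-trimmed if requested), plus its stop-to-stop extent.

    ``start``/``end`` are 1-based inclusive forward-strand positions of the
    first and last codon base of the (possibly Met-trimmed) ORF; on the
    minus strand start > end. ``run_start``/``run_end`` give the untrimmed
    stop-free run with the same convention. The bounding stop codon is
    excluded from coordinates and sequences.
    """

    scaffold_id: str
    start: int
    end: int
    strand: str
    frame: int
    nt_seq: str
    aa_seq: str
    table_id: int
    run_start: int = 0
    run_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if (abs(self.end - self.start) + 1) % 3:
            raise ValueError("ORF length not a multiple of 3")
        if len(self.aa_seq) * 3 != abs(self.end - self.start) + 1:
            raise ValueError("aa length inconsistent with coordinates")
        if STOP in self.aa_seq:
            raise ValueError("aa_seq contains a stop symbol")

    @property
    def forward_start(self) -> int:
        return min(self.start, self.end)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str, genetic_code: GeneticCode) -> str:
    """Translate an in-frame nucleotide string; N-containing codons → 'X',
    stops → '*'. Length must be a multiple of 3."""
    if len(nt_seq) % 3:
        raise TranslationError(f"length {len(nt_seq)} not divisible by 3")
    bad = set(nt_seq) - set(_BASES)
    if bad:
        raise TranslationError(f"non-ACGTN characters {sorted(bad)}")
    cmap = genetic_code.codon_map
    out = []
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i:i + 3]
        out.append("X" if "N" in codon else cmap[codon])
    return "".join(out)


def _codon_lut(genetic_code: GeneticCode) -> np.ndarray:
    """125-entry base-5 codon lookup (A,C,G,T,N); any-N codons map to 'X'."""
    lut = np.full(125, ord("X"), dtype=np.uint8)
    for codon, aa in genetic_code.codon_map.items():
        idx = (
            _BASE_INDEX[codon[0]] * 25
            + _BASE_INDEX[codon[1]] * 5
            + _BASE_INDEX[codon[2]]
        )
        lut[idx] = ord(aa)
    return lut


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = np.full(raw.shape, 4, dtype=np.uint8)
    for base, i in _BASE_INDEX.items():
        enc[raw == ord(base)] = i
    return enc


def _translate_frame(enc: np.ndarray, offset: int, lut: np.ndarray) -> str:
    usable = (len(enc) - offset) // 3
    if usable <= 0:
        return ""
    tri = enc[offset:offset + usable * 3].reshape(-1, 3)
    idx = tri[:, 0].astype(np.int32) * 25 + tri[:, 1] * 5 + tri[:, 2]
    return lut[idx].tobytes().decode("ascii")


def _runs_between_stops(aa: str) -> Iterable[tuple[int, int]]:
    """Yield (i, j) codon index ranges of maximal stop-free runs."""
    start = 0
    for k, c in enumerate(aa):
        if c == STOP:
            if k > start:
                yield start, k
            start = k + 1
    if len(aa) > start:
        yield start, len(aa)


def find_orfs(
    assembly: GenomeAssembly,
    genetic_code: GeneticCode,
    min_aa: int = 10,
    max_aa: int = 100,
    require_met: bool = True,
) -> list[OrfRecord]:
    """Scan all six frames of every scaffold for ORFs.

    Stop-to-stop runs (including runs ending at a scaffold edge) are
    Met-trimmed when ``require_met`` is set, then length-filtered to
    ``min_aa ≤ len ≤ max_aa`` inclusive. Output order is deterministic:
    scaffold, then forward start, then frame.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if max_aa < min_aa:
        raise ValueError("max_aa must be >= min_aa")
    lut = _codon_lut(genetic_code)
    records: list[OrfRecord] = []
    for sid, seq in assembly.scaffolds.items():
        L = len(seq)
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            enc = _encode(s)
            for offset in range(3):
                frame = offset + 1 + (3 if strand == "-" else 0)
                aa = _translate_frame(enc, offset, lut)
                for i, j in _runs_between_stops(aa):
                    m = i
                    if require_met:
                        rel = aa.find("M", i, j)
                        if rel < 0:
                            continue
                        m = rel
                    n_aa = j - m
                    if not (min_aa <= n_aa <= max_aa):
                        continue
                    # local (strand-sequence) 1-based coordinates
                    loc_start = offset + 3 * m + 1
                    loc_end = offset + 3 * j
                    run_loc_start = offset + 3 * i + 1
                    if strand == "+":
                        start, end = loc_start, loc_end
                        run_start, run_end = run_loc_start, loc_end
                    else:
                        start, end = L - loc_start + 1, L - loc_end + 1
                        run_start, run_end = L - run_loc_start + 1, L - loc_end + 1
                    nt = s[loc_start - 1:loc_end]
                    records.append(
                        OrfRecord(
                            scaffold_id=sid,
                            start=start,
                            end=end,
                            strand=strand,
                            frame=frame,
                            nt_seq=nt,
                            aa_seq=aa[m:j],
                            table_id=genetic_code.table_id,
                            run_start=run_start,
                            run_end=run_end,
                        )
                    )
    records.sort(key=lambda r: (r.scaffold_id, r.forward_start, r.frame))
    return records


def length_filter(orfs: Iterable[OrfRecord], min_aa: int, max_aa: int) -> list[OrfRecord]:
    """Keep ORFs whose peptide length lies in [min_aa, max_aa], inclusive."""
    return [o for o in orfs if min_aa <= len(o.aa_seq) <= max_aa]
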