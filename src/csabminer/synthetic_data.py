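"""Synthetic genome assemblies with planted defensin precursor genes.

Generates i.i.d.-nucleotide scaffolds at a configurable GC fraction and
plants reverse-translated precursor genes (signal peptide + mature CS-αβ
peptide) at known coordinates on both strands, recording a truth manifest
so recovery can be scored exactly. Under the ciliate nuclear code
(table 6) a configurable fraction of glutamine codons is forced to TAA/TAG
— the reassigned stops that make these genes invisible to standard-code
ORF calling, the central difficulty the miner exists to handle.

The background is i.i.d. (no repeats, isochores or codon bias) — adequate
for exercising scanning logic; see the methods note for what that does and
does not emulate. A seed is mandatory: every artifact is reproducible
bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import datasets
from .io_formats import GenomeAssembly
from .orf_mining import GeneticCode, reverse_complement, translate

__all__ = [
    "SyntheticConfig",
    "PlantedGene",
    "SyntheticTruth",
    "RecoveryScore",
    "random_background",
    "reverse_translate",
    "plant_gene",
    "make_synthetic_assembly",
    "score_recovery",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic assembly.

    Defaults match the screening scale the pipeline is validated at:
    5 scaffolds of ~100 kb, balanced GC, ciliate code with reassigned
    internal stops, 3 planted precursor genes alternating strands.
    """

    seed: int
    n_scaffolds: int = 5
    scaffold_length_range: tuple[int, int] = (100_000, 100_000)
    gc_fraction: float = 0.5
    table_id: int = 6
    n_planted: int = 3
    use_internal_reassigned_stops: bool = True
    reassigned_stop_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.scaffold_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad scaffold_length_range")


@dataclass(frozen=True)
class PlantedGene:
    scaffold_id: str
    start: int          # 1-based forward position of the first codon base
    end: int            # 1-based forward position of the last codon base
    strand: str
    precursor_seq: str
    signal_end: int     # last residue of the signal peptide (1-based)
    mature_seq: str


@dataclass(frozen=True)
class SyntheticTruth:
    planted: tuple[PlantedGene, ...] = ()

    def matures(self) -> list[str]:
        return [g.mature_seq for g in self.planted]


def random_background(config: SyntheticConfig) -> GenomeAssembly:
    """i.i.d. nucleotides at the configured GC; scaffolds named synth_1..n."""
    rng = np.random.default_rng(config.seed)
    p_gc = config.gc_fraction / 2.0
    p_at = (1.0 - config.gc_fraction) / 2.0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [p_at, p_gc, p_gc, p_at]
    lo, hi = config.scaffold_length_range
    scaffolds: dict[str, str] = {}
    for i in range(config.n_scaffolds):
        length = int(rng.integers(lo, hi + 1))
        draw = rng.choice(bases, size=length, p=probs)
        scaffolds[f"synth_{i + 1}"] = draw.tobytes().decode("ascii")
    return GenomeAssembly(scaffolds)


def _inverse_codon_map(code: GeneticCode) -> dict[str, list[str]]:
    inv: dict[str, list[str]] = {}
    for codon, aa in sorted(code.codon_map.items()):
        if aa != "*":
            inv.setdefault(aa, []).append(codon)
    return inv


def reverse_translate(
    peptide: str,
    code: GeneticCode,
    rng: np.random.Generator,
    use_internal_reassigned_stops: bool = False,
    reassigned_stop_fraction: float = 0.5,
) -> str:
    """Uniform synonymous codon choice under ``code`` (never a stop codon).

    With ``use_internal_reassigned_stops`` and a code in which TAA/TAG read
    as Gln (table 6), each Gln is encoded by TAA or TAG with the given
    probability — planting codons a standard-code scan reads as stops.
    """
    if "*" in peptide:
        raise ValueError("peptide contains a stop symbol")
    inv = _inverse_codon_map(code)
    reassigned = [c for c in ("TAA", "TAG") if code.codon_map.get(c) == "Q"]
    out = []
    for aa in peptide:
        if aa not in inv:
            raise ValueError(f"no codon for residue {aa!r} in table {code.table_id}")
        if (
            use_internal_reassigned_stops
            and aa == "Q"
            and reassigned
            and rng.random() < reassigned_stop_fraction
        ):
            out.append(reassigned[int(rng.integers(len(reassigned)))])
        else:
            choices = inv[aa]
            out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def plant_gene(
    assembly: GenomeAssembly,
    peptide_precursor: str,
    signal_end: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    scaffold_id: Optional[str] = None,
    strand: Optional[str] = None,
    position: Optional[int] = None,
) -> tuple[GenomeAssembly, PlantedGene]:
    """Overwrite a scaffold segment with STOP + gene + STOP and record truth.

    The flanking in-frame stops bound the stop-free run exactly at the gene,
    so the Met-trimmed ORF equals the precursor. ``position`` is the 0-based
    offset of the upstream stop codon on the forward strand.
    """
    code = GeneticCode.from_ncbi(config.table_id)
    stop = sorted(code.stop_codons)[-1]  # TGA in both tables 1 and 6
    gene_nt = reverse_translate(
        peptide_precursor,
        code,
        rng,
        use_internal_reassigned_stops=config.use_internal_reassigned_stops,
        reassigned_stop_fraction=config.reassigned_stop_fraction,
    )
    insert = stop + gene_nt + stop
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        insert = reverse_complement(insert)
    sids = list(assembly.scaffolds)
    if scaffold_id is None:
        scaffold_id = sids[int(rng.integers(len(sids)))]
    seq = assembly.scaffolds[scaffold_id]
    if len(seq) < len(insert):
        raise ValueError("scaffold too short for insert")
    if position is None:
        position = int(rng.integers(0, len(seq) - len(insert) + 1))
    new_seq = seq[:position] + insert + seq[position + len(insert):]
    scaffolds = dict(assembly.scaffolds)
    scaffolds[scaffold_id] = new_seq

    gene_len = 3 * len(peptide_precursor)
    if strand == "+":
        start = position + 3 + 1          # skip upstream stop; 1-based
        end = start + gene_len - 1
    else:
        # insert layout on forward strand: revcomp(stop+gene+stop);
        # the gene's first codon base sits at the far end.
        end = position + 3 + 1
        start = end + gene_len - 1
    truth = PlantedGene(
        scaffold_id=scaffold_id,
        start=start,
        end=end,
        strand=strand,
        precursor_seq=peptide_precursor,
        signal_end=signal_end,
        mature_seq=peptide_precursor[signal_end:],
    )
    # internal consistency: the planted span re-translates to the precursor
    lo, hi = min(start, end), max(start, end)
    span = new_seq[lo - 1:hi]
    if strand == "-":
        span = reverse_complement(span)
    assert translate(span, code) == peptide_precursor
    return GenomeAssembly(scaffolds), truth


#: Default plantable payloads: the two bundled defensin precursors.
DEFAULT_PAYLOADS: tuple[tuple[str, int], ...] = (
    (datasets.LSAMP1_PRECURSOR, datasets.SIGNAL_ENDS["LsAMP-1"]),
    (datasets.LSAMP2_PRECURSOR, datasets.SIGNAL_ENDS["LsAMP-2"]),
)


def make_synthetic_assembly(
    config: SyntheticConfig,
    payloads: tuple[tuple[str, int], ...] = DEFAULT_PAYLOADS,
) -> tuple[GenomeAssembly, SyntheticTruth]:
    """Background + ``n_planted`` genes cycled from ``payloads``, alternating
    strands and placed on distinct, non-overlapping slots."""
    assembly = random_background(config)
    rng = np.random.default_rng((config.seed, 0x9E3779B9))
    planted: list[PlantedGene] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    sids = list(assembly.scaffolds)
    for k in range(config.n_planted):
        precursor, signal_end = payloads[k % len(payloads)]
        strand = "+" if k % 2 == 0 else "-"
        sid = sids[k % len(sids)]
        ins_len = 3 * len(precursor) + 6
        for _ in range(100):
            pos = int(rng.integers(0, len(assembly.scaffolds[sid]) - ins_len + 1))
            if all(
                pos + ins_len <= s or pos >= e
                for s, e in occupied.get(sid, [])
            ):
                break
        else:  # pragma: no cover - would need absurdly dense planting
            raise RuntimeError("could not find a free slot for planting")
        occupied.setdefault(sid, []).append((pos, pos + ins_len))
        assembly, gene = plant_gene(
            assembly, precursor, signal_end, config, rng,
            scaffold_id=sid, strand=strand, position=pos,
        )
        planted.append(gene)
    return assembly, SyntheticTruth(tuple(planted))


@dataclass(frozen=True)
class RecoveryScore:
    precision: Optional[float]   # None when no candidates were reported
    recall: float
    n_true_positive: int
    n_false_positive: int
    n_false_negative: int
    matched: tuple[tuple[int, int], ...] = ()   # (candidate idx, truth idx)


def score_recovery(
    candidates,
    truth: SyntheticTruth,
    match_mode: str = "exact_mature_seq",
) -> RecoveryScore:
    """Precision/recall of reported candidates against the truth manifest.

    ``exact_mature_seq`` matches on the mature peptide string;
    ``coordinate_overlap`` matches on scaffold + strand + any coordinate
    overlap. Each truth entry is matchable at most once.
    """
    if match_mode not in ("exact_mature_seq", "coordinate_overlap"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    unmatched = list(range(len(truth.planted)))
    matched: list[tuple[int, int]] = []
    cand_list = list(candidates)
    for ci, cand in enumerate(cand_list):
        hit = None
        for ti in unmatched:
            g = truth.planted[ti]
            if match_mode == "exact_mature_seq":
                if cand.mature_seq == g.mature_seq:
                    hit = ti
                    break
            else:
                orf = cand.orf
                if orf.scaffold_id == g.scaffold_id and orf.strand == g.strand:
                    lo1, hi1 = sorted((orf.start, orf.end))
                    lo2, hi2 = sorted((g.start, g.end))
                    if lo1 <= hi2 and lo2 <= hi1:
                        hit = ti
                        break
        if hit is not None:
            unmatched.remove(hit)
            matched.append((ci, hit))
    tp = len(matched)
    fp = len(cand_list) - tp
    fn = len(truth.planted) - tp
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return RecoveryScore(precision, recall, tp, fp, fn, tuple(matched))
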