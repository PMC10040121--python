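"""The end-to-end defensin screening cascade.

Stage order is fixed: six-frame ORF calling with a 10–100 aa length window
→ detection (homology against a reference defensin set OR a hit of the
fuzzy cysteine profile, union by default) → signal peptide (found, then
removed) → no transmembrane domain → CS-αβ secondary-structure topology
(αββ or βαββ) → antimicrobial-activity consensus, in which a candidate
survives only if *every* configured activity predictor calls it an AMP
(unanimity, the false-positive guard).

External predictors (SignalP/Phobius/Psipred-class tools and the AMP
classifiers) are pluggable adapters. Two families ship: truth-aware stubs
driven by a synthetic-truth manifest (for offline, exactly-scorable runs)
and a clearly-labeled built-in signal-peptide heuristic. Adapter failures
mark the candidate ``stage_error``; they are never silently passed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .align import local_align
from .io_formats import GenomeAssembly, PeptideSet
from .motif_profile import MotifProfile, compile_profile, scan_profile
from .orf_mining import GeneticCode, OrfRecord, find_orfs
from .peptide_chem import PeptideAnnotation, annotate
from . import datasets

logger = logging.getLogger(__name__)

__all__ = [
    "StageVerdict",
    "PeptideCandidate",
    "PredictorAdapter",
    "ScreenConfig",
    "ConfigError",
    "run_screen",
    "consensus_amp",
    "topology_filter",
    "collapse_topology",
    "make_truth_stub_adapters",
    "make_permissive_adapters",
    "heuristic_signal_adapter",
]

#: Fixed cascade stage vocabulary, in execution order after ORF calling.
STAGE_NAMES = (
    "detection",
    "signal_peptide",
    "transmembrane",
    "secondary_structure",
    "amp_consensus",
)

ADAPTER_KINDS = ("signal_peptide", "transmembrane", "secondary_structure", "amp_score")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class StageVerdict:
    stage_name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class AdapterResult:
    """Payload returned by an adapter: pass/fail plus kind-specific data
    (signal_end for signal adapters, an H/E/C string for secondary
    structure, a score string for AMP predictors)."""

    passed: bool
    detail: str = ""
    signal_end: Optional[int] = None
    ss_string: Optional[str] = None


@dataclass(frozen=True)
class PredictorAdapter:
    """A named, deterministic, pure peptide → AdapterResult function."""

    name: str
    kind: str
    fn: Callable[[str], AdapterResult]

    def __post_init__(self) -> None:
        if self.kind not in ADAPTER_KINDS:
            raise ConfigError(f"unknown adapter kind {self.kind!r}")

    def __call__(self, peptide: str) -> AdapterResult:
        return self.fn(peptide)


@dataclass
class PeptideCandidate:
    orf: OrfRecord
    precursor_seq: str
    signal_end: Optional[int] = None
    mature_seq: Optional[str] = None
    verdicts: list[StageVerdict] = field(default_factory=list)
    annotation: Optional[PeptideAnnotation] = None
    best_hit: Optional[str] = None
    best_hit_pct_id: Optional[float] = None

    @property
    def reported(self) -> bool:
        """A candidate is reported iff it reached and passed every stage."""
        names = [v.stage_name for v in self.verdicts]
        return (
            all(v.passed for v in self.verdicts)
            and list(names) == list(STAGE_NAMES)
        )


@dataclass(frozen=True)
class ScreenConfig:
    """Cascade configuration (see module docstring for stage semantics)."""

    table_id: int = 6
    min_aa: int = 10
    max_aa: int = 100
    require_met: bool = True
    pattern_text: str = datasets.CSAB_PROFILE_TEXT
    reference_set: Optional[PeptideSet] = None
    combine_mode: str = "or"            # homology OR/AND profile
    homology_score_per_column: float = 2.0
    homology_min_pid: float = 30.0
    min_ss_run: int = 3

    def __post_init__(self) -> None:
        if self.combine_mode not in ("or", "and"):
            raise ConfigError(f"combine_mode must be 'or' or 'and'")


def consensus_amp(verdicts: Sequence[bool]) -> bool:
    """Unanimity rule: AMP iff every configured predictor says AMP."""
    if not verdicts:
        raise ConfigError("consensus_amp requires at least one AMP predictor verdict")
    return all(verdicts)


def collapse_topology(ss_string: str, min_run: int = 3) -> str:
    """Collapse a per-residue H/E/C string to its element sequence, dropping
    coil and runs shorter than ``min_run``."""
    bad = set(ss_string) - set("HEC")
    if bad:
        raise ValueError(f"secondary-structure string contains {sorted(bad)}")
    elements = []
    i = 0
    while i < len(ss_string):
        j = i
        while j < len(ss_string) and ss_string[j] == ss_string[i]:
            j += 1
        if ss_string[i] != "C" and (j - i) >= min_run:
            elements.append(ss_string[i])
        i = j
    return "".join(elements)


def topology_filter(ss_string: str, min_run: int = 3) -> bool:
    """True iff the element sequence is αββ (HEE) or βαββ (EHEE)."""
    return collapse_topology(ss_string, min_run) in ("HEE", "EHEE")


# ---------------------------------------------------------------------------
# bundled adapters

#: Kyte–Doolittle hydropathy, used by the built-in signal heuristic.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


def heuristic_signal_adapter(
    min_hydro: float = 1.5, window: tuple[int, int] = (6, 18), cleave_after: int = 20
) -> PredictorAdapter:
    """Built-in fallback signal-peptide heuristic (NOT a SignalP wrapper).

    Requires an initial Met and a hydrophobic core (mean Kyte–Doolittle over
    residues ``window`` ≥ ``min_hydro``); cleaves after ``cleave_after``
    residues. A coarse stand-in for exploratory runs only — calibrated
    correctness tests use truth-aware stubs instead.
    """

    def fn(precursor: str) -> AdapterResult:
        if not precursor.startswith("M") or len(precursor) <= cleave_after:
            return AdapterResult(False, "no Met start or too short")
        lo, hi = window
        core = precursor[lo - 1:hi]
        h = sum(_KD.get(c, 0.0) for c in core) / max(len(core), 1)
        if h < min_hydro:
            return AdapterResult(False, f"core hydropathy {h:.2f} < {min_hydro}")
        return AdapterResult(True, f"core hydropathy {h:.2f}", signal_end=cleave_after)

    return PredictorAdapter("heuristic-signal", "signal_peptide", fn)


#: Canonical βαββ secondary-structure string emitted by the truth stub.
_TRUTH_SS = "EEEE" + "C" + "HHHHHHHH" + "CC" + "EEEEE" + "CC" + "EEEEE"


def make_truth_stub_adapters(truth, n_amp: int = 3) -> list[PredictorAdapter]:
    """Truth-aware test stubs fed by a SyntheticTruth manifest.

    The signal stub recognizes planted precursors and returns their
    annotated cleavage boundary; the transmembrane, secondary-structure and
    the ``n_amp`` activity stubs pass exactly the planted mature peptides.
    Everything else fails — the behaviour of perfectly calibrated external
    predictors on data whose ground truth is known.
    """
    signal_by_precursor = {g.precursor_seq: g.signal_end for g in truth.planted}
    matures = {g.mature_seq for g in truth.planted}

    def signal_fn(precursor: str) -> AdapterResult:
        se = signal_by_precursor.get(precursor)
        if se is None:
            return AdapterResult(False, "no signal peptide")
        return AdapterResult(True, f"cleavage after {se}", signal_end=se)

    def tm_fn(mature: str) -> AdapterResult:
        return AdapterResult(mature in matures, "0 TM helices" if mature in matures else "TM-like")

    def ss_fn(mature: str) -> AdapterResult:
        if mature in matures:
            return AdapterResult(True, "βαββ", ss_string=_TRUTH_SS)
        return AdapterResult(False, "non-CSαβ topology", ss_string="C" * max(len(mature), 1))

    adapters = [
        PredictorAdapter("truth-signal", "signal_peptide", signal_fn),
        PredictorAdapter("truth-tm", "transmembrane", tm_fn),
        PredictorAdapter("truth-ss", "secondary_structure", ss_fn),
    ]
    for k in range(n_amp):
        def amp_fn(mature: str, _k=k) -> AdapterResult:
            ok = mature in matures
            return AdapterResult(ok, "AMP" if ok else "non-AMP")
        adapters.append(PredictorAdapter(f"truth-amp-{k + 1}", "amp_score", amp_fn))
    return adapters


def make_permissive_adapters(n_amp: int = 3) -> list[PredictorAdapter]:
    """Stubs that pass everything (signal_end None → mature = precursor).
    Reduces the cascade to ORF + detection + length stages."""
    ok = AdapterResult(True, "permissive")
    ss = AdapterResult(True, "permissive", ss_string=_TRUTH_SS)
    adapters = [
        PredictorAdapter("pass-signal", "signal_peptide", lambda p: ok),
        PredictorAdapter("pass-tm", "transmembrane", lambda p: ok),
        PredictorAdapter("pass-ss", "secondary_structure", lambda p: ss),
    ]
    for k in range(n_amp):
        adapters.append(PredictorAdapter(f"pass-amp-{k + 1}", "amp_score", lambda p: ok))
    return adapters


# ---------------------------------------------------------------------------
# cascade


def _detection_stage(
    cand: PeptideCandidate, config: ScreenConfig, profile: MotifProfile
) -> StageVerdict:
    profile_hit = bool(scan_profile(cand.precursor_seq, profile, mode="any"))
    homology_hit = False
    best = None
    if config.reference_set is not None:
        for rid, ref in config.reference_set.records.items():
            res = local_align(cand.precursor_seq, ref)
            cols = res.n_aligned_columns
            if cols == 0:
                continue
            if (
                res.score / cols >= config.homology_score_per_column
                and res.pid_columns >= config.homology_min_pid
            ):
                homology_hit = True
                if best is None or res.pid_columns > best[1]:
                    best = (rid, res.pid_columns)
    if best is not None:
        cand.best_hit, cand.best_hit_pct_id = best[0], round(best[1], 1)
    if config.combine_mode == "or":
        passed = profile_hit or homology_hit
    else:
        passed = profile_hit and (homology_hit or config.reference_set is None)
    detail = f"profile={'hit' if profile_hit else 'miss'},homology={'hit' if homology_hit else 'miss'}"
    return StageVerdict("detection", passed, detail)


def _run_adapter(adapter: PredictorAdapter, peptide: str, stage: str) -> tuple[Optional[AdapterResult], Optional[StageVerdict]]:
    try:
        return adapter(peptide), None
    except Exception as exc:  # noqa: BLE001 - adapter code is third-party
        logger.warning("adapter %s failed: %s", adapter.name, exc)
        return None, StageVerdict(stage, False, f"stage_error: {adapter.name}: {exc}")


def run_screen(
    assembly: GenomeAssembly,
    config: ScreenConfig,
    adapters: Sequence[PredictorAdapter],
) -> list[PeptideCandidate]:
    """Run the full cascade over an assembly.

    Returns every candidate that reached the detection stage, each carrying
    a verdict for every stage it reached (short-circuit after the first
    failure); the reported set is ``[c for c in out if c.reported]``.
    Output order follows ORF order and is deterministic.
    """
    by_kind: dict[str, list[PredictorAdapter]] = {k: [] for k in ADAPTER_KINDS}
    for a in adapters:
        by_kind[a.kind].append(a)
    for kind in ("signal_peptide", "transmembrane", "secondary_structure"):
        if len(by_kind[kind]) != 1:
            raise ConfigError(f"exactly one {kind} adapter required, got {len(by_kind[kind])}")
    if not by_kind["amp_score"]:
        raise ConfigError("at least one amp_score adapter required")

    code = GeneticCode.from_ncbi(config.table_id)
    profile = compile_profile(config.pattern_text)
    orfs = find_orfs(
        assembly, code,
        min_aa=config.min_aa, max_aa=config.max_aa, require_met=config.require_met,
    )
    out: list[PeptideCandidate] = []
    for orf in orfs:
        cand = PeptideCandidate(orf=orf, precursor_seq=orf.aa_seq)
        v = _detection_stage(cand, config, profile)
        cand.verdicts.append(v)
        out.append(cand)
        if not v.passed:
            continue

        # signal peptide: find, then remove
        res, err = _run_adapter(by_kind["signal_peptide"][0], cand.precursor_seq, "signal_peptide")
        if err:
            cand.verdicts.append(err)
            continue
        cand.verdicts.append(StageVerdict("signal_peptide", res.passed, res.detail))
        if not res.passed:
            continue
        cand.signal_end = res.signal_end
        cand.mature_seq = (
            cand.precursor_seq[res.signal_end:] if res.signal_end else cand.precursor_seq
        )

        res, err = _run_adapter(by_kind["transmembrane"][0], cand.mature_seq, "transmembrane")
        if err:
            cand.verdicts.append(err)
            continue
        cand.verdicts.append(StageVerdict("transmembrane", res.passed, res.detail))
        if not res.passed:
            continue

        res, err = _run_adapter(by_kind["secondary_structure"][0], cand.mature_seq, "secondary_structure")
        if err:
            cand.verdicts.append(err)
            continue
        ss_ok = res.passed and res.ss_string is not None and topology_filter(
            res.ss_string, config.min_ss_run
        )
        cand.verdicts.append(StageVerdict("secondary_structure", ss_ok, res.detail))
        if not ss_ok:
            continue

        amp_flags: list[bool] = []
        amp_error = None
        for a in by_kind["amp_score"]:
            res, err = _run_adapter(a, cand.mature_seq, "amp_consensus")
            if err:
                amp_error = err
                break
            amp_flags.append(res.passed)
        if amp_error:
            cand.verdicts.append(amp_error)
            continue
        cand.verdicts.append(
            StageVerdict(
                "amp_consensus",
                consensus_amp(amp_flags),
                f"{sum(amp_flags)}/{len(amp_flags)} predictors AMP",
            )
        )
        if cand.verdicts[-1].passed:
            cand.annotation = annotate(cand.mature_seq)
    return out


def reported(candidates: Sequence[PeptideCandidate]) -> list[PeptideCandidate]:
    """Candidates that passed every stage."""
    return [c for c in candidates if c.reported]
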