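"""Fuzzy cysteine-profile compiler and scanner (fuzzpro-equivalent).

The CS-αβ defensin family is recognized not by overall similarity but by
the spacing of its six structural cysteines. That spacing is written as a
PROSITE-like pattern of fixed residues, bounded wildcard gaps (``Xm-n``,
bare ``X`` = exactly one residue) and single-position ambiguity classes
(``[GAPSIDERYW]``). The shipped default pattern is
``CX2−18CX3CX2−10[GAPSIDERYW]X1CX4−17CXC``.

Both ASCII hyphen-minus and the typographic minus/en-dash are accepted in
range subscripts and canonicalized on compile.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Literal, Optional

__all__ = [
    "ProfileElement",
    "MotifProfile",
    "MotifMatch",
    "ProfileParseError",
    "compile_profile",
    "scan_profile",
    "find_gamma_core",
    "gamma_core_c_terminal_most",
]

_DASHES = {"-", "−", "–"}  # hyphen-minus, minus sign, en-dash
_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


class ProfileParseError(ValueError):
    """Malformed pattern text; carries the 1-based column of the offence."""

    def __init__(self, message: str, column: int):
        super().__init__(f"column {column}: {message}")
        self.column = column


@dataclass(frozen=True)
class ProfileElement:
    kind: Literal["fixed", "gap", "class"]
    residue: Optional[str] = None
    min_len: int = 0
    max_len: int = 0
    members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind == "fixed" and not self.residue:
            raise ValueError("fixed element needs a residue")
        if self.kind == "gap" and not (0 <= self.min_len <= self.max_len):
            raise ValueError("gap element needs 0 <= min <= max")
        if self.kind == "class" and not self.members:
            raise ValueError("class element needs members")

    def render(self) -> str:
        if self.kind == "fixed":
            return self.residue  # type: ignore[return-value]
        if self.kind == "class":
            return "[" + "".join(sorted(self.members)) + "]"
        if self.min_len == self.max_len:
            return "X" if self.min_len == 1 else f"X{self.min_len}"
        return f"X{self.min_len}-{self.max_len}"


@dataclass(frozen=True)
class MotifProfile:
    elements: tuple[ProfileElement, ...]
    source_text: str

    def render(self) -> str:
        """Canonical pattern text (ASCII hyphens); recompiles to itself."""
        return "".join(e.render() for e in self.elements)

    @property
    def n_anchors(self) -> int:
        return sum(1 for e in self.elements if e.kind != "gap")


@dataclass(frozen=True)
class MotifMatch:
    """One profile occurrence: 1-based inclusive span plus the positions of
    every non-gap (fixed/class) element, in pattern order."""

    seq_id: str
    start: int
    end: int
    anchors: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.anchors, self.anchors[1:])):
            raise ValueError("anchors must be strictly increasing")


def compile_profile(pattern_text: str) -> MotifProfile:
    """Compile pattern text into an ordered element list.

    Grammar: residue letters are fixed elements; ``X`` optionally followed
    by ``m`` or ``m-n`` is a bounded gap (bare ``X`` = exactly one);
    ``[...]`` is a one-residue ambiguity class. Errors report the column.
    """
    text = pattern_text.strip()
    if not text:
        raise ProfileParseError("empty pattern", 1)
    elements: list[ProfileElement] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        col = i + 1
        if c == "X":
            i += 1
            lo_s = ""
            while i < n and text[i].isdigit():
                lo_s += text[i]
                i += 1
            if lo_s and i < n and text[i] in _DASHES:
                i += 1
                hi_s = ""
                while i < n and text[i].isdigit():
                    hi_s += text[i]
                    i += 1
                if not hi_s:
                    raise ProfileParseError("range is missing its upper bound", i + 1)
                lo, hi = int(lo_s), int(hi_s)
            elif lo_s:
                lo = hi = int(lo_s)
            else:
                lo = hi = 1
            if lo > hi:
                raise ProfileParseError(f"range min {lo} exceeds max {hi}", col)
            elements.append(ProfileElement("gap", min_len=lo, max_len=hi))
        elif c == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise ProfileParseError("unclosed '['", col)
            members = text[i + 1:j]
            bad = set(members) - _AA_LETTERS
            if not members or bad:
                raise ProfileParseError(
                    f"bad class contents {members!r}", col
                )
            elements.append(ProfileElement("class", members=frozenset(members)))
            i = j + 1
        elif c in _AA_LETTERS:
            elements.append(ProfileElement("fixed", residue=c))
            i += 1
        else:
            raise ProfileParseError(f"unexpected character {c!r}", col)
    return MotifProfile(tuple(elements), pattern_text)


def _element_matches(elem: ProfileElement, residue: str) -> bool:
    if elem.kind == "fixed":
        return residue == elem.residue
    return residue in elem.members


def _match_any_from(peptide: str, elements: tuple[ProfileElement, ...]) -> bool:
    """Existence check via memoized descent: does any start position admit a
    full match? O(len · elements · max_gap)."""
    n = len(peptide)

    @lru_cache(maxsize=None)
    def ok(pos: int, ei: int) -> bool:
        if ei == len(elements):
            return True
        e = elements[ei]
        if e.kind == "gap":
            hi = min(e.max_len, n - pos)
            return any(ok(pos + g, ei + 1) for g in range(e.min_len, hi + 1))
        if pos >= n or not _element_matches(e, peptide[pos]):
            return False
        return ok(pos + 1, ei + 1)

    result = any(ok(s, 0) for s in range(n))
    ok.cache_clear()
    return result


def _enumerate_matches(
    seq_id: str, peptide: str, elements: tuple[ProfileElement, ...]
) -> Iterator[MotifMatch]:
    """Backtracking enumeration of all distinct anchor vectors, every start."""
    n = len(peptide)

    def rec(pos: int, ei: int, anchors: list[int]) -> Iterator[tuple[int, tuple[int, ...]]]:
        if ei == len(elements):
            yield pos, tuple(anchors)
            return
        e = elements[ei]
        if e.kind == "gap":
            hi = min(e.max_len, n - pos)
            for g in range(e.min_len, hi + 1):
                yield from rec(pos + g, ei + 1, anchors)
            return
        if pos < n and _element_matches(e, peptide[pos]):
            anchors.append(pos + 1)
            yield from rec(pos + 1, ei + 1, anchors)
            anchors.pop()

    seen: set[tuple[int, tuple[int, ...]]] = set()
    for s in range(n):
        for end_pos, anchors in rec(s, 0, []):
            key = (s + 1, anchors)
            if key in seen:
                continue
            seen.add(key)
            yield MotifMatch(seq_id=seq_id, start=s + 1, end=end_pos, anchors=anchors)


def scan_profile(
    peptide: str,
    profile: MotifProfile,
    mode: str = "all",
    seq_id: str = "",
    max_matches: Optional[int] = 100_000,
):
    """Scan one peptide against a compiled profile.

    mode='any'            → bool (memoized existence check, cheap);
    mode='all'            → every distinct match (anchor-vector dedup);
    mode='first_per_start'→ at most one match per start position.

    Enumeration is capped at ``max_matches`` (degenerate inputs such as
    poly-Cys admit combinatorially many anchor vectors).
    """
    if not peptide:
        raise ValueError("empty peptide")
    if mode == "any":
        return _match_any_from(peptide, profile.elements)
    if mode not in ("all", "first_per_start"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[MotifMatch] = []
    last_start = None
    for m in _enumerate_matches(seq_id, peptide, profile.elements):
        if mode == "first_per_start":
            if m.start == last_start:
                continue
            last_start = m.start
        out.append(m)
        if max_matches is not None and len(out) >= max_matches:
            break
    return out


_GAMMA_CORE = compile_profile("GXCX3-9C")


def find_gamma_core(peptide: str, seq_id: str = "") -> list[MotifMatch]:
    """All occurrences of the γ-core signature Gly-X-Cys-X(3..9)-Cys."""
    if not peptide:
        return []
    return scan_profile(peptide, _GAMMA_CORE, mode="all", seq_id=seq_id)


def gamma_core_c_terminal_most(peptide: str, seq_id: str = "") -> Optional[MotifMatch]:
    """The C-terminal-most γ-core instance, or None.

    Ranked by start position (the motif sits at the C-terminus of CS-αβ
    defensins); among instances sharing a start, the nearest closing Cys
    wins — the terminal cysteine of the motif is read as the first
    downstream cysteine, not an arbitrarily distant one.
    """
    matches = find_gamma_core(peptide, seq_id=seq_id)
    if not matches:
        return None
    return max(matches, key=lambda m: (m.start, -m.end))
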