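# Methods

This note documents the models, conventions and design choices behind
`csabminer`, in the order the pipeline applies them.

## ORF model and coordinates

An ORF is a **maximal stop-free codon run** bounded by in-frame stop
codons or by scaffold ends (stop-to-stop). Runs that touch a scaffold edge
are reported because draft-assembly scaffolds truncate genes. With
`require_met` (default on) the run is trimmed to its **first** Met and
discarded if it has none; a run whose Met-trimmed peptide falls outside
the 10–100 aa window is dropped, not re-trimmed to a later Met. Both the
Met-trimmed coordinates and the untrimmed run extent are carried on each
record (`start`/`end` vs `run_start`/`run_end`), so users can inspect
cases where a published coordinate span reflects the stop-to-stop run
rather than the Met-trimmed product.

Coordinates are 1-based inclusive on the forward strand; minus-strand
features are reported with `start > end` (`start` is always the first
codon base), rendered as `[977 - 771]` in output tables. Codons containing
N translate to `X` and are never treated as stops; ORFs containing `X` are
kept and filtered only by stages that require clean sequence.

Genetic codes come from the NCBI tables via Biopython (table 1 standard,
table 6 ciliate/dasycladacean: TAA→Q, TAG→Q, TGA the only stop);
user-supplied 64-codon maps are accepted. Automatic genetic-code inference
is out of scope — the caller states the table.

The six-frame scan is vectorized (base-5 codon indexing into a 125-entry
lookup), processing ~2 Mb/s of assembly per core including profile
scanning; the validation suite therefore runs on full-scale (100 kb)
scaffolds rather than toys.

## Fuzzy profile grammar and scanner

The profile grammar covers fixed residues, bounded wildcard gaps `Xm-n`
(bare `X` = exactly one residue; `Xm` = exactly m) and single-position
ambiguity classes `[...]`. Both ASCII hyphen-minus and typographic
minus/en-dash are accepted in ranges and canonicalized on compile
(pattern files copied from typeset documents routinely carry U+2212). The
shipped CS-αβ pattern compiles to 13 elements with six fixed Cys anchors.
`X1` after the ambiguity class is read as **exactly one** residue — the
reading consistent with both reference defensins matching. PROSITE's full
grammar (N/C anchors, class repetition) is deliberately not implemented.

Scanning is backtracking enumeration from every start position. The
existence verdict (`mode="any"`, what the screening cascade uses) is
memoized over (position, element) and costs O(length · elements ·
max-gap). Full enumeration deduplicates by anchor vector and is capped
(default 100 000 matches) because degenerate inputs such as poly-Cys admit
combinatorially many anchor placements. The scanner is validated against
an independently written bounded-quantifier regular expression on random
peptides; both must agree on every verdict.

**γ-core selection.** All occurrences of Gly‑X‑Cys‑X₃₋₉‑Cys are
enumerated. Because the gap wildcard may itself cover a cysteine, several
instances can share a start; the "C-terminal-most" instance is defined as
the one with the greatest start position, breaking ties toward the
**nearest** closing Cys — the motif's terminal cysteine is read as the
first downstream cysteine, not an arbitrarily distant one. On the
reference defensins this yields the span 30–40 on both matures.

## Net charge

The headline model is deliberately minimal: +1 per Lys/Arg, −1 per
Asp/Glu, His neutral at pH 7, the termini contributing +1 and −1 (net 0),
`X` contributing 0. This is the convention that reproduces the published
integer charges of both reference defensins (−1 and −5) exactly; since no
charge convention is ever universal, the continuous Henderson–Hasselbalch
model (side chains D, E, C, Y, H, K, R plus termini; EMBOSS or Lehninger
pKa sets) is provided alongside and agrees with the integer model within
±1.5 charge units for both reference peptides.

Cysteine-framework labels ("1-4,2-5,3-6"; the ten-cysteine reference-array
form "C2-C6, C3-C8, C4-C9") are sequence-order assignments under the
CS-αβ assumption, emitted only for exactly-six-cysteine peptides. They are
classification labels, not geometry: structure-derived bridges come from
`structure_tools.detect_disulfides`. Recomputing the ten-position array
from its defining reference alignment is a documented limitation.

## Alignment and identity

Alignments use Biopython's PairwiseAligner (Needleman–Wunsch and
Smith–Waterman, affine gaps, end gaps penalized in global mode). The gap
convention is: first gap residue costs `gap_open` (default 10), each
further residue `gap_extend` (default 1), BLOSUM62 by default. The
headline identity metric is **identities / shorter raw length**
(`pid_shorter`); identities / alignment columns is reported alongside.
Among co-optimal alignments the identity count can depend on which
alignment is enumerated first, so inputs are canonicalized
lexicographically before alignment and swapped back — making scores *and*
identity counts exactly symmetric in the argument order. The DP is
validated against an exhaustive path-recursion oracle on short peptides.

The screening cascade's homology stage uses in-core Smith–Waterman
against a user-supplied reference FASTA with a score-per-aligned-column
threshold (default 2.0) plus a minimum column identity (default 30%),
**not** BLAST E-values — there are no database statistics in-core. An
adapter slot allows wiring a real BLAST run where E-value semantics are
needed. Homology and profile detection combine as a union by default
(`combine_mode="or"`), configurable to intersection.

## Screening cascade semantics

Stage order is fixed (detection → signal peptide → transmembrane →
secondary structure → AMP consensus); configurable ordering was rejected
to keep verdict semantics stable. Detection runs on the ORF peptide
(precursor); all later stages run on the mature peptide after signal
cleavage. Candidates short-circuit at their first failing stage but retain
verdicts for every stage reached; "reported" means all stages passed.
Adapter exceptions produce a failed `stage_error` verdict — a broken
predictor can never silently pass a candidate. The unanimity rule requires
at least one configured AMP predictor; zero predictors is a configuration
error, not a vacuous pass.

The topology filter collapses per-residue H/E/C strings to an element
sequence, dropping coil and runs shorter than `min_ss_run` (default 3
residues — shorter "elements" are prediction noise), and accepts exactly
HEE (αββ) or EHEE (βαββ).

The built-in signal-peptide heuristic (Met start + mean Kyte–Doolittle
hydropathy ≥ 1.5 over residues 6–18 + fixed cleavage after residue 20) is
a coarse, clearly-labeled fallback for exploratory CLI runs. Calibrated
correctness claims never rely on it; they use truth-aware stubs.

## Synthetic genomes: what they do and do not emulate

The generator emulates the *screening conditions*: multi-scaffold
assemblies (default 5 × 100 kb), i.i.d. nucleotides at a set GC fraction
(default 0.5), and secreted-peptide precursor genes (the two bundled
defensin precursors by default) planted on both strands with flanking
in-frame stops, reverse-translated with uniform synonymous codon choice
under the target code. Under table 6, half of the glutamine codons are
forced to TAA/TAG by default (`reassigned_stop_fraction = 0.5`) —
the reassigned stops that truncate standard-code translation. A seed is
mandatory; generation is bit-for-bit reproducible.

Not emulated: codon bias, repeats, isochores, and the architecture of
ciliate macronuclear genomes (nanochromosomes, telomeres, scrambled
genes). Passing recovery tests therefore demonstrates the correctness of
the scanning and bookkeeping logic under realistic scale and composition
— not robustness to the full messiness of real assemblies or to imperfect
external predictors.

Measured on this background, the fuzzy profile alone has a false-positive
floor of roughly 0.25 hits per Mb of GC-0.5 background among 10–100 aa
ORFs (≈5 hits in 20 Mb). The profile stage is a coarse sieve by design;
the "zero reports on pure background" guarantee holds for the full
cascade, whose downstream stages (signal peptide, topology, unanimity)
remove such background hits.

## Structural distances and trees

PDB parsing takes the first model and altloc A; Cα defines the trace, Cys
Sγ the disulfide geometry. Disulfides are greedy minimal-distance Sγ–Sγ
matching under 2.5 Å (the canonical S–S bond is ~2.05 Å; 2.5 Å clears it
without reaching non-bonded contacts), each Cys in at most one bridge.

Pairwise structure distances are Kabsch RMSD over Cα pairs matched by
global sequence alignment (or positionally, for equal-length sets). This
is a transparent stand-in for structure-alignment servers (Dali-class
Z-scores): it changes the distances, so published tree topologies built
from such servers are not expected to be reproduced — only the internal
correctness of superposition, distance and tree construction is claimed,
and is what the tests enforce. Kabsch uses SVD with the determinant-sign
correction, so only proper rotations are returned.

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion; ties break deterministically toward the lexicographically
lowest label pair; negative branch-length estimates are clamped to zero
with a log entry; n = 2 splits the single distance in half. On additive
matrices the generating tree is recovered exactly (topology and branch
lengths); on arbitrary matrices the implementation agrees with
scikit-bio's independent NJ to 1e-8 in patristic distances. Monophyly
queries are answered on the unrooted tree via bipartitions: a subset is a
clade under a given outgroup rooting iff some edge separates exactly that
subset.

## Problem sizes in the validation suite

The suite validates at the scale the method is meant for: 20 seeded
assemblies of 500 kb (recovery), 20 × 1 Mb of pure background
(false-positive floor), 10 000 random peptides (scanner/oracle
equivalence), 200 random trees of up to 8 taxa (NJ), 1 000 random point
sets (Kabsch). The full suite completes in well under a minute on one
core.
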