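# csabminer

Genome mining of **cysteine-stabilized αβ (CS-αβ) defensins** in organisms
with non-standard nuclear genetic codes — in particular ciliates, whose
genomes read the canonical stop codons TAA/TAG as glutamine (NCBI
translation table 6). Standard ORF callers truncate ciliate genes at those
reassigned codons, which is how small antimicrobial-peptide genes stay
invisible in public assemblies. `csabminer` is for researchers who want to
prospect draft genome assemblies for these peptides with a transparent,
fully offline, reproducible pipeline.

## What it does

CS-αβ defensins are small (~34–54 aa) secreted peptides: an α-helix packed
against a two-stranded β-sheet, locked by three disulfide bridges in the
sequence-order pattern Cys1–Cys4, Cys2–Cys5, Cys3–Cys6, with a C-terminal
**γ-core** signature Gly‑X‑Cys‑X₃₋₉‑Cys. The family is recognized not by
overall similarity but by the spacing of its six structural cysteines,
written as a PROSITE-like fuzzy pattern:

```
C X(2,18) C X(3) C X(2,10) [GAPSIDERYW] X C X(4,17) C X C
```

The pipeline stages:

1. **ORF mining** — six-frame stop-to-stop extraction under a selectable
   genetic code (tables 1 and 6 built in, arbitrary codon maps accepted),
   Met-trimmed, length-filtered to 10–100 aa.
2. **Detection** — the fuzzy cysteine profile (a backtracking scanner with
   bounded gaps) and/or local-alignment homology against a reference
   defensin set; union by default.
3. **Cascade** — signal-peptide presence (then removal), no transmembrane
   domain, CS-αβ topology (αββ or βαββ after collapsing a per-residue
   H/E/C string), and an antimicrobial-activity **unanimity rule**: a
   candidate survives only if *every* configured activity predictor calls
   it an AMP. External predictors are pluggable adapters; truth-aware
   stubs make the cascade exactly scorable offline.
4. **Characterization** — net charge (integer and Henderson–Hasselbalch
   models), cysteine framework and bridge labels, γ-core location,
   percent identity (Needleman–Wunsch / Smith–Waterman, BLOSUM62).
5. **Structural clustering** — Cα traces from PDB, geometric disulfide
   detection (Sγ–Sγ ≤ 2.5 Å), Kabsch superposition RMSD distance
   matrices, Saitou–Nei neighbor-joining trees with newick export.
6. **Synthetic genomes** — seeded i.i.d. scaffolds with defensin precursor
   genes planted at known coordinates on both strands (optionally encoding
   glutamines as TAA/TAG), so recovery precision/recall can be scored
   exactly.

## Worked example

The package ships the two *Laurentiella* sp. defensin precursors
(LsAMP-1, LsAMP-2) as reference fixtures:

```python
from csabminer import datasets
from csabminer.align import global_align
from csabminer.peptide_chem import annotate

for name, mature in datasets.lsamp_matures().items():
    a = annotate(mature)
    print(name, a.length_aa, a.net_charge_integer, a.cys_positions, a.gamma_core_span)

res = global_align(datasets.LSAMP1_MATURE, datasets.LSAMP2_MATURE)
print(f"{res.n_identical} identities -> {res.pid_shorter:.1f}%")
```

prints

```
LsAMP-1 44 -1 (7, 18, 22, 32, 40, 42) (30, 40)
LsAMP-2 46 -5 (7, 18, 22, 32, 40, 42) (30, 40)
27 identities -> 61.4%
```

i.e. two anionic mature peptides (net charges −1 and −5 at pH 7), each
with the six cysteines of the CS-αβ framework at identical positions, a
γ-core ending at Cys40, and 61% mutual sequence identity.

A full mining round trip from the shell:

```bash
csab-miner simulate --seed 11 --out-dir sim      # 5x100 kb + 3 planted genes
csab-miner screen --fasta sim/assembly.fasta --out-dir screened
csab-miner orfs --fasta sim/assembly.fasta --table 6 --out-prefix orfs
csab-miner scan --fasta orfs.faa --gamma-core
```

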