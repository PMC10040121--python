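"""Light structural analytics: PDB parsing, disulfide geometry, Kabsch
superposition, RMSD distance matrices and neighbor-joining trees.

The structural clustering route here is deliberately simple: residue
correspondences come from global sequence alignment, distances are Kabsch
RMSD over matched Cα atoms, and trees are Saitou–Nei neighbor joining.
This is a transparent, fully reproducible stand-in for heavyweight
structure-alignment servers; absolute tree topologies from such servers
are not expected to be reproduced exactly (see the methods note).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .align import global_align

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "DistanceMatrix",
    "PhyloNode",
    "PhyloTree",
    "parse_pdb",
    "detect_disulfides",
    "kabsch_rmsd",
    "kabsch_superpose",
    "pairwise_structure_distances",
    "neighbor_joining",
    "is_monophyletic",
]


class PDBFormatError(ValueError):
    pass


@dataclass(frozen=True)
class StructureModel:
    """Cα trace plus Cys Sγ positions for one structure (first model,
    altloc A preferred)."""

    model_id: str
    residues: tuple[tuple[str, int, str], ...]   # (resname, resnum, chain)
    ca_coords: np.ndarray                        # (n, 3) float64, Å
    sg_coords: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.ca_coords):
            raise ValueError("one Cα per residue required")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite coordinates")

    def sequence(self) -> str:
        return "".join(
            protein_letters_3to1.get(resname.capitalize().upper(), "X")
            for resname, _, _ in self.residues
        )


def parse_pdb(path, model_id: Optional[str] = None) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Uses the first MODEL of multi-model (NMR-style) files; among altlocs
    the blank/'A' location is taken. Residues without a Cα (waters,
    ligands) are skipped; a file yielding no Cα at all is a format error.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(model_id or "model", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise PDBFormatError(f"no models in {path}") from None
    residues: list[tuple[str, int, str]] = []
    ca: list[np.ndarray] = []
    sg: dict[int, np.ndarray] = {}
    for chain in model:
        for res in chain:
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                atom = atom.disordered_get("A")
            residues.append((res.get_resname().strip(), res.get_id()[1], chain.id))
            ca.append(np.asarray(atom.get_coord(), dtype=float))
            if res.get_resname().strip() == "CYS" and "SG" in res:
                s = res["SG"]
                if s.is_disordered():
                    s = s.disordered_get("A")
                sg[res.get_id()[1]] = np.asarray(s.get_coord(), dtype=float)
    if not ca:
        raise PDBFormatError(f"no Cα atoms in {path}")
    return StructureModel(
        model_id=model_id or str(path),
        residues=tuple(residues),
        ca_coords=np.vstack(ca),
        sg_coords=sg,
    )


def detect_disulfides(
    model: StructureModel, cutoff_angstrom: float = 2.5
) -> list[tuple[int, int]]:
    """Greedy minimal-distance Sγ–Sγ matching under a distance cutoff.

    Each cysteine joins at most one bridge; pairs are returned sorted by
    residue number. 2.5 Å comfortably covers the ~2.05 Å S–S bond without
    reaching into non-bonded contacts.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    nums = sorted(model.sg_coords)
    dists = []
    for i, a in enumerate(nums):
        for b in nums[i + 1:]:
            d = float(np.linalg.norm(model.sg_coords[a] - model.sg_coords[b]))
            if d <= cutoff_angstrom:
                dists.append((d, a, b))
    dists.sort()
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, a, b in dists:
        if a in used or b in used:
            continue
        used.update((a, b))
        pairs.append((a, b))
    return sorted(pairs)


def bridge_label(model: StructureModel, pairs: Sequence[tuple[int, int]]) -> str:
    """Render bridges as sequence-order cysteine indices, e.g. '1-4,2-5,3-6'."""
    order = {num: i + 1 for i, num in enumerate(sorted(model.sg_coords))}
    return ",".join(f"{order[a]}-{order[b]}" for a, b in sorted(pairs))


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of B onto A (rotation R, translation t).

    Proper rotation is enforced by the determinant sign correction; returns
    (R, t, rmsd) with ``A ≈ B @ R.T + t`` at minimal RMSD.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {A.shape} vs {B.shape}")
    if len(A) < 3:
        raise ValueError("need at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - cb @ R.T
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / len(A)))
    return R, t, rmsd


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimized RMSD (Å) after optimal rigid superposition."""
    return kabsch_superpose(coords_a, coords_b)[2]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.isnan(D).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(D, D.T, atol=1e-9):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-9):
            raise ValueError("nonzero diagonal")
        if (D < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "D", D)


def pairwise_structure_distances(
    models: Sequence[StructureModel], pairing_mode: str = "sequence_align_then_ca"
) -> DistanceMatrix:
    """All-pairs Kabsch-RMSD distance matrix over a set of structures.

    ``sequence_align_then_ca``: residue correspondence from a global
    sequence alignment of the Cα-bearing residues, RMSD over matched Cα.
    ``equal_length_direct``: positional 1:1 pairing (models must agree in
    length). Any pair with fewer than 3 matched residues is an error.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    if pairing_mode not in ("sequence_align_then_ca", "equal_length_direct"):
        raise ValueError(f"unknown pairing_mode {pairing_mode!r}")
    n = len(models)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = models[i], models[j]
            if pairing_mode == "equal_length_direct":
                if len(a.ca_coords) != len(b.ca_coords):
                    raise ValueError(f"length mismatch for pair ({a.model_id}, {b.model_id})")
                pa, pb = a.ca_coords, b.ca_coords
            else:
                res = global_align(a.sequence(), b.sequence())
                ia = ib = 0
                idx_a, idx_b = [], []
                for x, y in zip(res.aligned_a, res.aligned_b):
                    if x != "-" and y != "-":
                        idx_a.append(ia)
                        idx_b.append(ib)
                    if x != "-":
                        ia += 1
                    if y != "-":
                        ib += 1
                if len(idx_a) < 3:
                    raise ValueError(
                        f"fewer than 3 matched residues for pair ({a.model_id}, {b.model_id})"
                    )
                pa, pb = a.ca_coords[idx_a], b.ca_coords[idx_b]
            D[i, j] = D[j, i] = kabsch_rmsd(pa, pb)
    return DistanceMatrix(tuple(m.model_id for m in models), D)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class PhyloNode:
    name: Optional[str] = None
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at an arbitrary internal node."""

    root: PhyloNode

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(n: PhyloNode) -> None:
            if n.is_leaf:
                out.append(n.name)
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return out

    def newick(self) -> str:
        def fmt(n: PhyloNode) -> str:
            if n.is_leaf:
                return n.name or ""
            inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in n.children)
            return f"({inner})"

        return fmt(self.root) + ";"

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the leaf set on the child side
        of an internal edge."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()

        def walk(n: PhyloNode) -> frozenset[str]:
            if n.is_leaf:
                return frozenset([n.name])
            below = frozenset()
            for c, _ in n.children:
                side = walk(c)
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(min(side, all_leaves - side, key=sorted))
                below |= side
            return below

        walk(self.root)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        leaves = sorted(self.leaf_names())
        idx = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        D = np.zeros((n, n))

        def walk(node: PhyloNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            sides: list[dict[str, float]] = []
            for child, bl in node.children:
                side = {k: v + bl for k, v in walk(child).items()}
                sides.append(side)
            for i_s in range(len(sides)):
                for j_s in range(i_s + 1, len(sides)):
                    for la, da in sides[i_s].items():
                        for lb, db in sides[j_s].items():
                            D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = da + db
            for side in sides:
                below.update(side)
            return below

        walk(self.root)
        return DistanceMatrix(tuple(leaves), D)


def _clamp(x: float, context: str) -> float:
    if x < 0:
        logger.info("negative branch length %.4g clamped to 0 (%s)", x, context)
        return 0.0
    return x


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Deterministic tie-break: among equal-Q pairs the lexicographically
    lowest (label, label) pair joins first. Negative branch-length
    estimates are clamped to zero (logged). n = 2 yields a single edge
    split d/2, d/2.
    """
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[str, PhyloNode] = {lab: PhyloNode(name=lab) for lab in labels}
    # active distance map on current node keys
    d: dict[frozenset[str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d[frozenset((a, b))] = float(dm.D[i, labels.index(b)])

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    active = sorted(labels)
    step = 0
    if len(active) == 2:
        a, b = active
        half = dist(a, b) / 2.0
        root = PhyloNode(children=[(nodes[a], _clamp(half, "n=2")), (nodes[b], _clamp(half, "n=2"))])
        return PhyloTree(root)

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        la = _clamp(la, f"join({a},{b})")
        lb = _clamp(lb, f"join({a},{b})")
        new_key = f"@internal{step}"
        step += 1
        nodes[new_key] = PhyloNode(children=[(nodes[a], la), (nodes[b], lb)])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_key, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = sorted([c for c in active if c not in (a, b)] + [new_key])

    a, b, c = active
    la = _clamp(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)), "final")
    lb = _clamp(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)), "final")
    lc = _clamp(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)), "final")
    root = PhyloNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root)


def is_monophyletic(tree: PhyloTree, leaf_subset, outgroup_leaf: str) -> bool:
    """True iff ``leaf_subset`` forms a clade when the tree is rooted on
    ``outgroup_leaf``.

    Equivalent split criterion on the unrooted tree: some edge separates
    exactly ``leaf_subset`` from everything else (including the outgroup).
    """
    subset = frozenset(leaf_subset)
    leaves = frozenset(tree.leaf_names())
    unknown = (subset | {outgroup_leaf}) - leaves
    if unknown:
        raise ValueError(f"unknown leaves {sorted(unknown)}")
    if outgroup_leaf in subset:
        raise ValueError("outgroup must be outside the subset")
    if len(subset) in (1, len(leaves) - 1):
        return True  # trivial splits always exist
    comp = leaves - subset
    canonical = min(subset, comp, key=sorted)
    return canonical in tree.splits()
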