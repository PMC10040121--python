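import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csabminer.structure_tools import (
    DistanceMatrix,
    PhyloNode,
    PhyloTree,
    PDBFormatError,
    bridge_label,
    detect_disulfides,
    is_monophyletic,
    kabsch_rmsd,
    neighbor_joining,
    pairwise_structure_distances,
    parse_pdb,
)


def _res(resname, num, ca, sg=None):
    atoms = {"CA": ca}
    if sg is not None:
        atoms["SG"] = sg
    return (resname, num, atoms)


def _random_rigid(rng):
    """Random proper rotation (QR-based) + translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.normal(scale=20.0, size=3)


class TestParsePdb:
    def test_three_residue_trace(self, write_pdb):
        path = write_pdb([
            _res("ALA", 1, (0.0, 0.0, 0.0)),
            _res("GLY", 2, (3.8, 0.0, 0.0)),
            _res("SER", 3, (7.6, 0.0, 0.0)),
        ])
        model = parse_pdb(path)
        assert len(model.ca_coords) == 3
        assert model.sequence() == "AGS"

    def test_cysteine_sg_extracted(self, write_pdb):
        path = write_pdb([
            _res("CYS", 1, (0.0, 0.0, 0.0), sg=(1.0, 1.0, 1.0)),
            _res("ALA", 2, (3.8, 0.0, 0.0)),
            _res("CYS", 3, (7.6, 0.0, 0.0), sg=(2.0, 1.0, 1.0)),
        ])
        model = parse_pdb(path)
        assert sorted(model.sg_coords) == [1, 3]

    def test_multi_model_uses_first(self, tmp_path):
        from conftest import make_pdb_text

        body1 = make_pdb_text([_res("ALA", 1, (0.0, 0.0, 0.0)),
                               _res("GLY", 2, (3.8, 0.0, 0.0)),
                               _res("SER", 3, (7.6, 0.0, 0.0))]).replace("END\n", "")
        body2 = make_pdb_text([_res("ALA", 1, (9.0, 9.0, 9.0)),
                               _res("GLY", 2, (12.8, 9.0, 9.0)),
                               _res("SER", 3, (16.6, 9.0, 9.0))]).replace("END\n", "")
        text = "MODEL     1\n" + body1 + "ENDMDL\nMODEL     2\n" + body2 + "ENDMDL\nEND\n"
        p = tmp_path / "nmr.pdb"
        p.write_text(text)
        model = parse_pdb(p)
        assert np.allclose(model.ca_coords[0], [0.0, 0.0, 0.0])

    def test_no_ca_is_format_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(PDBFormatError):
            parse_pdb(p)


class TestDetectDisulfides:
    def test_canonical_bond_length_pairs(self, write_pdb):
        path = write_pdb([
            _res("CYS", 1, (0.0, 0.0, 0.0), sg=(0.0, 0.0, 0.0)),
            _res("CYS", 2, (3.8, 0.0, 0.0), sg=(2.05, 0.0, 0.0)),
            _res("ALA", 3, (7.6, 0.0, 0.0)),
        ])
        assert detect_disulfides(parse_pdb(path)) == [(1, 2)]

    def test_distant_sulfurs_unpaired(self, write_pdb):
        path = write_pdb([
            _res("CYS", 1, (0.0, 0.0, 0.0), sg=(0.0, 0.0, 0.0)),
            _res("CYS", 2, (3.8, 0.0, 0.0), sg=(6.0, 0.0, 0.0)),
            _res("ALA", 3, (7.6, 0.0, 0.0)),
        ])
        assert detect_disulfides(parse_pdb(path)) == []

    def test_csab_geometry_yields_1_4_2_5_3_6(self, write_pdb):
        # Sγ positions built so cysteines pair (1,4), (2,5), (3,6) at 2.05 Å
        sg = {
            1: (0.0, 0.0, 0.0), 4: (2.05, 0.0, 0.0),
            2: (10.0, 0.0, 0.0), 5: (10.0, 2.05, 0.0),
            3: (20.0, 0.0, 0.0), 6: (20.0, 0.0, 2.05),
        }
        residues = [
            _res("CYS", num, (float(num) * 3.8, 0.0, 0.0), sg=sg[num])
            for num in range(1, 7)
        ]
        model = parse_pdb(write_pdb(residues))
        pairs = detect_disulfides(model)
        assert pairs == [(1, 4), (2, 5), (3, 6)]
        assert bridge_label(model, pairs) == "1-4,2-5,3-6"


class TestKabsch:
    def test_identical_sets_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance_and_symmetry(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            pts = rng.normal(scale=5.0, size=(n, 3))
            R, t = _random_rigid(rng)
            moved = pts @ R.T + t
            assert kabsch_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-9)
            other = rng.normal(scale=5.0, size=(n, 3))
            assert kabsch_rmsd(pts, other) == pytest.approx(kabsch_rmsd(other, pts), abs=1e-9)

    def test_single_displacement_upper_bound(self, rng):
        """One point displaced by d among N anchored points: optimal RMSD
        cannot exceed d/sqrt(N) (achieved without moving the frame)."""
        for _ in range(20):
            n = int(rng.integers(4, 25))
            pts = rng.normal(scale=5.0, size=(n, 3))
            d = float(rng.uniform(0.5, 4.0))
            moved = pts.copy()
            moved[0] += d * np.array([1.0, 0.0, 0.0])
            assert kabsch_rmsd(pts, moved) <= d / np.sqrt(n) + 1e-9

    def test_mismatched_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestPairwiseDistances:
    def _model_pdbs(self, write_pdb, rng):
        base = [
            _res("ALA", 1, (0.0, 0.0, 0.0)),
            _res("GLY", 2, (3.8, 0.0, 0.0)),
            _res("CYS", 3, (5.0, 3.0, 0.0), sg=(6.0, 4.0, 0.0)),
            _res("SER", 4, (7.6, 3.8, 1.0)),
        ]
        R, t = _random_rigid(rng)
        moved = [
            (name, num, {an: tuple(np.array(xyz) @ R.T + t) for an, xyz in atoms.items()})
            for name, num, atoms in base
        ]
        return (
            parse_pdb(write_pdb(base, "a.pdb"), model_id="a"),
            parse_pdb(write_pdb(moved, "b.pdb"), model_id="b"),
        )

    def test_rigid_copies_have_zero_distance(self, write_pdb, rng):
        a, b = self._model_pdbs(write_pdb, rng)
        dm = pairwise_structure_distances([a, b])
        # PDB text carries 0.001 Å precision, which bounds attainable RMSD
        assert dm.D[0, 1] == pytest.approx(0.0, abs=2e-3)

    def test_hand_computed_three_model_matrix(self, write_pdb, rng):
        a, b = self._model_pdbs(write_pdb, rng)
        # c: model a with its last Cα displaced by 2.0 Å -> RMSD vs a is
        # bounded above by 2/sqrt(4) = 1.0 and strictly positive
        shifted = [
            _res("ALA", 1, (0.0, 0.0, 0.0)),
            _res("GLY", 2, (3.8, 0.0, 0.0)),
            _res("CYS", 3, (5.0, 3.0, 0.0), sg=(6.0, 4.0, 0.0)),
            _res("SER", 4, (7.6, 3.8, 3.0)),
        ]
        c = parse_pdb(write_pdb(shifted, "c.pdb"), model_id="c")
        dm = pairwise_structure_distances([a, b, c])
        assert dm.labels == ("a", "b", "c")
        assert np.allclose(dm.D, dm.D.T)
        assert dm.D[0, 1] == pytest.approx(0.0, abs=2e-3)
        assert 0.0 < dm.D[0, 2] <= 1.0 + 1e-6
        assert dm.D[1, 2] == pytest.approx(dm.D[0, 2], abs=2e-3)


def _random_additive_tree(rng, n):
    """Random bifurcating tree with uniform branch lengths; returns
    (PhyloTree, DistanceMatrix of its exact leaf distances)."""
    nodes = [PhyloNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = PhyloNode(children=[
            (nodes[i], float(rng.uniform(0.1, 1.0))),
            (nodes[j], float(rng.uniform(0.1, 1.0))),
        ])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = PhyloNode(children=[(x, float(rng.uniform(0.1, 1.0))) for x in nodes])
    tree = PhyloTree(root)
    return tree, tree.leaf_distances()


class TestNeighborJoining:
    def test_two_taxa_split_in_half(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = neighbor_joining(dm)
        (ca, la), (cb, lb) = tree.root.children
        assert {ca.name, cb.name} == {"A", "B"}
        assert la == lb == 0.5

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) with internal edge 1
        tree = PhyloTree(PhyloNode(children=[
            (PhyloNode(children=[(PhyloNode(name="A"), 1.0), (PhyloNode(name="B"), 2.0)]), 1.0),
            (PhyloNode(children=[(PhyloNode(name="C"), 3.0), (PhyloNode(name="D"), 4.0)]), 0.0),
        ]))
        dm = tree.leaf_distances()
        out = neighbor_joining(dm)
        assert out.splits() == {frozenset({"A", "B"})}
        assert np.allclose(out.leaf_distances().D, dm.D, atol=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=4, max_value=8), st.integers(min_value=0, max_value=10_000))
    def test_additive_matrices_reconstructed_exactly(self, n, seed):
        rng = np.random.default_rng(seed)
        true_tree, dm = _random_additive_tree(rng, n)
        out = neighbor_joining(dm)
        assert out.splits() == true_tree.splits()
        assert np.allclose(out.leaf_distances().D, dm.D, atol=1e-8)

    def test_agrees_with_independent_nj_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 7))
            M = rng.uniform(0.5, 3.0, size=(n, n))
            M = (M + M.T) / 2.0
            np.fill_diagonal(M, 0.0)
            labels = tuple(f"t{i}" for i in range(n))
            mine = neighbor_joining(DistanceMatrix(labels, M)).leaf_distances()
            sk = skbio.tree.nj(skbio.DistanceMatrix(M, ids=labels))
            ids = sorted(labels)
            sk_d = np.array([[sk.find(a).distance(sk.find(b)) for b in ids] for a in ids])
            assert np.allclose(mine.D, sk_d, atol=1e-8)

    def test_nan_rejected(self):
        M = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), M)


class TestMonophyly:
    def _quartet(self):
        return PhyloTree(PhyloNode(children=[
            (PhyloNode(children=[(PhyloNode(name="A"), 1.0), (PhyloNode(name="B"), 1.0)]), 1.0),
            (PhyloNode(name="C"), 1.0),
            (PhyloNode(name="D"), 1.0),
        ]))

    def test_sister_pair_is_clade(self):
        assert is_monophyletic(self._quartet(), {"A", "B"}, "D") is True

    def test_split_pair_is_not(self):
        assert is_monophyletic(self._quartet(), {"A", "C"}, "D") is False

    def test_complement_of_outgroup_is_trivially_a_clade(self):
        assert is_monophyletic(self._quartet(), {"A", "B", "C"}, "D") is True

    def test_unknown_leaf_rejected(self):
        with pytest.raises(ValueError):
            is_monophyletic(self._quartet(), {"A", "Z"}, "D")
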