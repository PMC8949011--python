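"""Tree building: pseudo-distances, UPGMA, NJ, sequence distances."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from structphy.simdata import (
    EvolutionParams,
    evolve_family,
    generate_backbone,
    random_ultrametric_tree,
)
from structphy.structio import SequenceRecord
from structphy.treebuild import (
    hierarchical_tree,
    nj_tree,
    pairwise_sequence_identity,
    pseudo_distance,
    sequence_distance_matrix,
    structural_distance_matrix,
    zscore_matrix,
    conservation_table,
    leaf_annotation_table,
)


class TestPseudoDistance:
    def test_hand_arithmetic(self):
        assert pseudo_distance(30, 30, 30) == 0.0
        assert pseudo_distance(30, 20, 10) == pytest.approx(30.0)

    def test_negative_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert pseudo_distance(10, 10, 11) == 0.0

    def test_non_positive_self_z(self):
        with pytest.raises(ValueError):
            pseudo_distance(0, 10, 5)


class TestStructuralDistanceMatrix:
    def test_three_copies_near_zero(self, backbone60):
        copies = []
        for i in range(3):
            s = generate_backbone(60, seed=99)
            s.id = f"c{i}"
            copies.append(s)
        D = structural_distance_matrix(copies)
        off = D.data[np.triu_indices(3, k=1)]
        assert np.all(off < 1e-6)

    def test_symmetric_zero_diagonal(self):
        structures = []
        for i in range(3):
            s = generate_backbone(50, seed=200 + i)
            s.id = f"s{i}"
            structures.append(s)
        D = structural_distance_matrix(structures)
        assert np.allclose(D.data, D.data.T)
        assert np.all(np.diag(D.data) == 0)

    def test_zscore_matrix_symmetrised(self):
        structures = []
        for i in range(3):
            s = generate_backbone(50, seed=300 + i)
            s.id = f"s{i}"
            structures.append(s)
        Z = zscore_matrix(structures)
        assert np.allclose(Z.to_numpy(), Z.to_numpy().T, equal_nan=True)
        assert (np.diag(Z.to_numpy()) > 0).all()

    def test_two_family_separation(self):
        """Within-family < between-family distances in >= 90% of 20 seeds."""
        hits = 0
        for seed in range(20):
            structures = []
            for fam in range(2):
                root = generate_backbone(60, seed=7000 + 2 * seed + fam)
                tree = random_ultrametric_tree(
                    2, seed=7100 + 2 * seed + fam, depth=1.0,
                    names=[f"f{fam}a", f"f{fam}b"])
                params = EvolutionParams(
                    tree=tree, coordinate_noise_rate=0.5,
                    substitution_rate=0.5, hinge_probability=0.0,
                    seed=7200 + 2 * seed + fam)
                structures += [s for s, _ in evolve_family(root, params)]
            D = structural_distance_matrix(structures)
            within = max(D["f0a", "f0b"], D["f1a", "f1b"])
            between = min(D["f0a", "f1a"], D["f0a", "f1b"],
                          D["f0b", "f1a"], D["f0b", "f1b"])
            if within < between:
                hits += 1
        assert hits >= 18

    def test_needs_three(self, backbone60):
        with pytest.raises(ValueError):
            structural_distance_matrix([backbone60, backbone60])


class TestHierarchicalTree:
    def test_hand_upgma(self):
        D = DistanceMatrix(np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0.0]]),
                           ["A", "B", "C"])
        t = hierarchical_tree(D)
        # topology ((A,B),C); A-B merge height 0.5, root height 2.0
        ab = t.lca(["A", "B"])
        assert sorted(x.name for x in ab.tips()) == ["A", "B"]
        assert t.find("A").length == pytest.approx(0.5)
        assert t.find("C").length == pytest.approx(2.0)
        assert ab.length == pytest.approx(1.5)

    def test_two_leaves_cherry(self):
        D = DistanceMatrix(np.array([[0, 3], [3, 0.0]]), ["A", "B"])
        t = hierarchical_tree(D)
        assert sorted(x.name for x in t.tips()) == ["A", "B"]
        assert t.find("A").length == pytest.approx(1.5)

    def test_tie_break_deterministic(self):
        D = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ["d", "c", "b", "a"])
        trees = {str(hierarchical_tree(D)) for _ in range(5)}
        assert len(trees) == 1
        # first merge is the lexicographically smallest pair (a, b)
        t = hierarchical_tree(D)
        ab = t.lca(["a", "b"])
        assert sorted(x.name for x in ab.tips()) == ["a", "b"]

    def test_ultrametric_exact_recovery(self):
        for seed in range(5):
            true = random_ultrametric_tree(6, seed=seed, depth=2.0)
            D = true.tip_tip_distances()
            est = hierarchical_tree(D)
            assert true.compare_rfd(est) == 0
            D2 = est.tip_tip_distances().filter(D.ids)
            assert np.allclose(D2.data, D.data, atol=1e-9)

    def test_linkage_options(self):
        D = DistanceMatrix(np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0.0]]),
                           ["A", "B", "C"])
        for linkage in ("average", "complete", "single"):
            t = hierarchical_tree(D, linkage=linkage)
            assert sorted(x.name for x in t.tips()) == ["A", "B", "C"]
        with pytest.raises(ValueError):
            hierarchical_tree(D, linkage="ward")

    def test_scipy_cross_check(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        n = 7
        M = rng.uniform(1, 10, size=(n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        ids = [f"t{i}" for i in range(n)]
        t = hierarchical_tree(DistanceMatrix(M, ids))
        # merge heights must match scipy's linkage heights (as multisets);
        # our node height is the tip-to-node path length, scipy's is the
        # inter-cluster distance = 2 * height
        Zs = average(squareform(M))
        ours = sorted(np.round(sorted(Zs[:, 2]), 9))
        mine = []
        for node in t.non_tips(include_self=True):
            tip = next(node.tips())
            h = 0.0
            cur = tip
            while cur is not node:
                h += cur.length
                cur = cur.parent
            mine.append(round(2 * h, 9))
        assert sorted(mine) == pytest.approx(sorted(ours), abs=1e-6)


class TestSequenceDistances:
    def test_identical_zero(self):
        ident, cols = pairwise_sequence_identity("ACDEFGHIKL", "ACDEFGHIKL")
        assert ident == 1.0
        assert cols == 10

    def test_one_substitution(self):
        ident, _ = pairwise_sequence_identity("ACDEFGHIKL", "ACDEFGHIKV")
        assert 1.0 - ident == pytest.approx(0.1)

    def test_matrix_symmetric(self):
        seqs = [SequenceRecord("a", "ACDEFGHIKLMN"),
                SequenceRecord("b", "ACDEFGHIKVMN"),
                SequenceRecord("c", "WYWYWYWYWYWY")]
        D = sequence_distance_matrix(seqs)
        assert np.allclose(D.data, D.data.T)
        assert np.all(np.diag(D.data) == 0)

    def test_duplicate_ids(self):
        seqs = [SequenceRecord("a", "ACDEFGHIKL")] * 3
        with pytest.raises(ValueError):
            sequence_distance_matrix(seqs)


class TestNJ:
    def test_hand_additive_four_taxon(self):
        D = DistanceMatrix(np.array([
            [0, 2, 6, 7],
            [2, 0, 6, 7],
            [6, 6, 0, 3],
            [7, 7, 3, 0.0],
        ]), ["A", "B", "C", "D"])
        t = nj_tree(D)
        # topology AB|CD
        ab = t.lca(["A", "B"])
        assert sorted(x.name for x in ab.tips()) == ["A", "B"]
        # additive: tip-tip distances reproduced exactly
        back = t.tip_tip_distances().filter(D.ids)
        assert np.allclose(back.data, D.data, atol=1e-9)

    def test_three_taxon_star(self):
        D = DistanceMatrix(np.array([[0, 4, 4], [4, 0, 4], [4, 4, 0.0]]),
                           ["A", "B", "C"])
        t = nj_tree(D)
        back = t.tip_tip_distances().filter(D.ids)
        assert np.allclose(back.data, D.data, atol=1e-9)

    @staticmethod
    def _bipartitions(tree):
        """Non-trivial unrooted bipartitions, normalised to exclude one tip."""
        tips = {t.name for t in tree.tips()}
        ref = min(tips)
        parts = set()
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(tips - side)
            if 2 <= len(side) <= len(tips) - 2:
                parts.add(side)
        return parts

    def test_round_trip_from_random_tree(self):
        # NJ trees are unrooted: compare unrooted bipartition sets
        for seed in range(5):
            true = random_ultrametric_tree(7, seed=100 + seed, depth=2.0)
            D = true.tip_tip_distances()
            est = nj_tree(D)
            assert self._bipartitions(true) == self._bipartitions(est)

    def test_no_negative_branches(self, rng):
        M = rng.uniform(1, 10, size=(6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        t = nj_tree(DistanceMatrix(M, [f"t{i}" for i in range(6)]))
        for node in t.traverse(include_self=False):
            assert node.length is None or node.length >= 0


class TestTables:
    def test_conservation(self):
        seqs = [SequenceRecord("a", "AAC"), SequenceRecord("b", "AWC"),
                SequenceRecord("c", "AWW")]
        tab = conservation_table(seqs)
        assert list(tab["conservation"]) == pytest.approx([1.0, 2 / 3, 2 / 3])
        with pytest.raises(ValueError):
            conservation_table([SequenceRecord("a", "AA"),
                                SequenceRecord("b", "AAA")])

    def test_leaf_annotations(self):
        import pandas as pd
        ann = pd.DataFrame({"id": ["x", "y"], "category": ["u", "v"]})
        tab = leaf_annotation_table(["y", "x"], ann)
        assert list(tab["category"]) == ["v", "u"]
        with pytest.raises(ValueError):
            leaf_annotation_table(["z"], ann)
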