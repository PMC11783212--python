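from dataclasses import replace

import numpy as np
import pytest

from ssapkit import phylo
from ssapkit.phylo import (SimilarityMatrix, average_linkage, cut_tree,
                           select_representatives, sequence_similarity_matrix,
                           similarity_matrix, to_newick)
from ssapkit.structio import StructureSet
from ssapkit.superpose import align_structures
from ssapkit.synthetic_data import FAMILY_PRESETS, make_ssap_monomer


def upgma_oracle(ids, D):
    """Textbook UPGMA recomputing cluster distances from scratch each
    step (independent of the incremental implementation).  Returns the
    merge sequence [(frozenset_a, frozenset_b, height), ...]."""
    clusters = [frozenset([i]) for i in ids]
    merges = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                a, b = clusters[x], clusters[y]
                d = np.mean([D[ids.index(p), ids.index(q)]
                             for p in a for q in b])
                key = (d, tuple(sorted((min(a), min(b)))))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, _), x, y = best
        a, b = clusters[x], clusters[y]
        merges.append((a, b, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(a | b)
    return merges


def tree_merges(tree):
    """Extract (leafset_a, leafset_b, height) in merge order."""
    internals = []

    def walk(node):
        if node.is_leaf:
            return
        internals.append(node)
        for c in node.children:
            walk(c)

    walk(tree.root)
    internals.sort(key=lambda n: n.merge_index)
    return [(frozenset(n.children[0].leaf_labels()),
             frozenset(n.children[1].leaf_labels()), n.height)
            for n in internals]


def _sim_from_dist(ids, D):
    return SimilarityMatrix(ids=ids, values=1.0 - D)


class TestSimilarityMatrix:
    def test_identical_structures_score_one(self, long_monomer):
        m, _ = long_monomer
        twin = m.transformed(np.eye(3), np.zeros(3), new_id="twin")
        s = StructureSet(members=[m, twin])
        sim = similarity_matrix(s)
        assert sim.values[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_pairwise_calls(
            self, long_monomer, short_monomer):
        a, _ = long_monomer
        b, _ = short_monomer
        c, _ = make_ssap_monomer(
            replace(FAMILY_PRESETS["sak3-like"], seed=8), "sak")
        sim = similarity_matrix(StructureSet(members=[a, b, c]))
        for i, x in enumerate((a, b, c)):
            for j, y in enumerate((a, b, c)):
                if i < j:
                    res = align_structures(x, y)
                    expect = 0.5 * (res.tm_norm_a + res.tm_norm_b)
                    assert sim.values[i, j] == pytest.approx(expect, abs=1e-9)

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            SimilarityMatrix(ids=["a", "b"],
                             values=np.array([[1.0, 0.2], [0.4, 1.0]]))

    def test_needs_two(self, long_monomer):
        m, _ = long_monomer
        with pytest.raises(ValueError):
            similarity_matrix(StructureSet(members=[m]))


class TestAverageLinkage:
    def test_hand_worked_three_leaf_case(self):
        #  d(A,B)=0.1, d(A,C)=d(B,C)=0.5
        D = np.array([[0.0, 0.1, 0.5],
                      [0.1, 0.0, 0.5],
                      [0.5, 0.5, 0.0]])
        tree = average_linkage(_sim_from_dist(["A", "B", "C"], D))
        merges = tree_merges(tree)
        assert merges[0] == (frozenset("A"), frozenset("B"), pytest.approx(0.1))
        assert merges[1][2] == pytest.approx(0.5)
        assert merges[1][0] | merges[1][1] == frozenset("ABC")

    def test_identical_structures_merge_at_zero(self):
        D = np.array([[0.0, 0.0, 0.4],
                      [0.0, 0.0, 0.4],
                      [0.4, 0.4, 0.0]])
        tree = average_linkage(_sim_from_dist(["A", "B", "C"], D))
        assert tree_merges(tree)[0][2] == pytest.approx(0.0)

    @pytest.mark.parametrize("n_leaves", [4, 6, 8])
    def test_matches_textbook_oracle(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for trial in range(10):
            ids = [f"L{i}" for i in range(n_leaves)]
            D = rng.uniform(0.05, 0.95, size=(n_leaves, n_leaves))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = average_linkage(_sim_from_dist(ids, D))
            got = tree_merges(tree)
            expected = upgma_oracle(ids, D)
            for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
                assert {ga, gb} == {ea, eb}
                assert gh == pytest.approx(eh, abs=1e-9)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(77)
        n = 7
        D = rng.uniform(0.1, 0.9, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tree = average_linkage(_sim_from_dist([f"x{i}" for i in range(n)], D))
        heights = [h for _, _, h in tree_merges(tree)]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


class TestNewick:
    def test_two_leaf_branch_lengths(self):
        D = np.array([[0.0, 0.2], [0.2, 0.0]])
        tree = average_linkage(_sim_from_dist(["A", "B"], D))
        assert to_newick(tree) == "(A:0.1,B:0.1);"

    def test_single_leaf(self):
        from ssapkit.phylo import ClusterTree, TreeNode
        assert to_newick(ClusterTree(root=TreeNode(label="A"))) == "A;"

    def test_roundtrip_parse(self):
        import skbio
        rng = np.random.default_rng(13)
        n = 6
        D = rng.uniform(0.1, 0.9, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"t{i}" for i in range(n)]
        tree = average_linkage(_sim_from_dist(ids, D))
        parsed = skbio.TreeNode.read([to_newick(tree)])
        assert sorted(t.name for t in parsed.tips()) == ids
        # ultrametric: all leaves equidistant from the root
        root_height = tree.root.height / 2
        for tip in parsed.tips():
            assert tip.distance(parsed) == pytest.approx(root_height)


class TestRepresentatives:
    def test_k_equals_leaf_count(self):
        D = np.array([[0.0, 0.3, 0.6],
                      [0.3, 0.0, 0.5],
                      [0.6, 0.5, 0.0]])
        sim = _sim_from_dist(["A", "B", "C"], D)
        tree = average_linkage(sim)
        reps = select_representatives(tree, sim, 3)
        assert sorted(reps.representatives) == ["A", "B", "C"]

    def test_k_out_of_range(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        sim = _sim_from_dist(["A", "B"], D)
        tree = average_linkage(sim)
        with pytest.raises(ValueError):
            cut_tree(tree, 3)
        with pytest.raises(ValueError):
            cut_tree(tree, 0)

    def test_medoid_matches_bruteforce(self):
        rng = np.random.default_rng(55)
        n = 5
        V = rng.uniform(0.5, 0.95, size=(n, n))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 1.0)
        ids = [f"m{i}" for i in range(n)]
        sim = SimilarityMatrix(ids=ids, values=V)
        tree = average_linkage(sim)
        reps = select_representatives(tree, sim, 1)
        means = [(np.mean([V[i, j] for j in range(n) if j != i]), ids[i])
                 for i in range(n)]
        expected = max(means, key=lambda t: (t[0], [-ord(c) for c in t[1]]))
        assert reps.representatives == [expected[1]]

    def test_two_family_recovery(self, two_family_set):
        sset, _ = two_family_set
        sim = similarity_matrix(sset)
        tree = average_linkage(sim)
        reps = select_representatives(tree, sim, 2)
        families = {sset.labels[r] for r in reps.representatives}
        assert families == {"rad52-long", "sak3-like"}
        # each cluster coincides with a generator family
        for cluster_idx in set(reps.clusters.values()):
            labs = {sset.labels[i] for i in reps.members_of(cluster_idx)}
            assert len(labs) == 1

    def test_representative_belongs_to_cluster(self, two_family_set):
        sset, _ = two_family_set
        sim = similarity_matrix(sset)
        tree = average_linkage(sim)
        reps = select_representatives(tree, sim, 2)
        for rep in reps.representatives:
            assert rep in reps.clusters


class TestSequenceSimilarity:
    def test_identical_sequences(self):
        seqs = [("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
                ("b", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")]
        sim = sequence_similarity_matrix(seqs)
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_half_sequence_directional_score(self):
        full = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"
        half = full[:16]
        score = phylo._identity_coverage(_default_aligner(), full, half)
        assert score == pytest.approx(0.5, abs=0.02)

    def test_half_sequence_symmetrized(self):
        full = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"
        sim = sequence_similarity_matrix([("f", full), ("h", full[:16])])
        # mean of 0.5 (query=full) and 1.0 (query=half)
        assert sim.values[0, 1] == pytest.approx(0.75, abs=0.02)

    def test_random_pair_matches_independent_recomputation(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        s1 = "".join(rng.choice(aas, 40))
        s2 = "".join(rng.choice(aas, 50))
        sim = sequence_similarity_matrix([("x", s1), ("y", s2)])

        aligner = _default_aligner()

        def score(q, s):
            aln = aligner.align(q, s)[0]
            ident = aln.counts().identities / aln.length
            cov = min(1.0, aln.length / len(q))
            return ident * cov

        expected = 0.5 * (score(s1, s2) + score(s2, s1))
        assert sim.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_similarity_matrix([("a", ""), ("b", "MKT")])


def _default_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner
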