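"""Alignment, identity matrices, UPGMA and bootstrap supports."""

import inspect
import random
from functools import lru_cache

import numpy as np
import pytest

from levigene.comparative import (
    DistanceMatrix,
    TreeNode,
    align_multi,
    bootstrap_tree,
    global_align,
    identity_matrix,
    p_distance_matrix,
    protein_params,
    rna_params,
    upgma,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_affine_score(a, b, score, go, ge):
    """Exhaustive best score over all global alignments with affine gaps.

    State-space DP over (i, j, state) with explicit enumeration semantics:
    identical to walking every monotone alignment path.
    """

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 start/diag, 1 gap-in-b open, 2 gap-in-a open
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = ge if state == 1 else go
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = ge if state == 2 else go
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


class TestGlobalAlign:
    def test_self_alignment_is_full_identity(self):
        aln = global_align("MKVLIVE", "MKVLIVE", protein_params())
        assert aln.identity_pct == 100.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_disjoint_rna_identity_zero(self):
        aln = global_align("AAAA", "CCCC", rna_params())
        assert aln.n_identical == 0
        assert aln.identity_pct == 0.0

    def test_score_matches_path_enumeration_oracle(self):
        random.seed(41)
        pp = protein_params()
        for _ in range(40):
            a = "".join(random.choice(AAS) for _ in range(random.randint(1, 12)))
            b = "".join(random.choice(AAS) for _ in range(random.randint(1, 12)))
            want = brute_force_affine_score(a, b, pp.score, pp.gap_open, pp.gap_extend)
            got = global_align(a, b, pp)
            assert got.score == pytest.approx(want), (a, b)

    def test_score_matches_biopython_aligner(self):
        # independent full implementation of the same scoring scheme
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        pp = protein_params()
        random.seed(42)
        for _ in range(40):
            a = "".join(random.choice(AAS) for _ in range(random.randint(3, 30)))
            b = "".join(random.choice(AAS) for _ in range(random.randint(3, 30)))
            assert global_align(a, b, pp).score == pytest.approx(aligner.score(a, b))

    def test_score_symmetric(self):
        random.seed(43)
        pp = protein_params()
        for _ in range(20):
            a = "".join(random.choice(AAS) for _ in range(random.randint(2, 20)))
            b = "".join(random.choice(AAS) for _ in range(random.randint(2, 20)))
            assert global_align(a, b, pp).score == pytest.approx(
                global_align(b, a, pp).score
            )

    def test_ungapping_recovers_inputs(self):
        aln = global_align("MKVLIVESSS", "MKVLESSS", protein_params())
        assert aln.aligned_a.replace("-", "") == "MKVLIVESSS"
        assert aln.aligned_b.replace("-", "") == "MKVLESSS"

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            global_align("MKVL", "AUGC1", protein_params())


class TestIdentityMatrix:
    def test_identical_pair_zero_distance(self):
        dm = identity_matrix(["MKVL", "MKVL"], params=protein_params())
        assert np.allclose(dm.d, 0.0)

    def test_hand_computed_three_sequences(self):
        # gap-free alignments: identities 3/4, 2/4, 1/4
        seqs = ["MKVL", "MKVI", "MRVI"]
        dm = identity_matrix(seqs, ["a", "b", "c"], protein_params())
        assert dm.d[0, 1] == pytest.approx(1 - 3 / 4)
        assert dm.d[1, 2] == pytest.approx(1 - 3 / 4)
        assert dm.d[0, 2] == pytest.approx(1 - 2 / 4)

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            identity_matrix(["MKVL"])


class TestUPGMA:
    def test_two_taxa_forced_tree(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        t = upgma(dm)
        assert t.height == pytest.approx(0.2)
        assert t.leaf_names() == frozenset({"A", "B"})

    def test_three_taxon_worked_example(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        t = upgma(DistanceMatrix(["A", "B", "C"], d))
        assert t.height == pytest.approx(0.3)
        (inner,) = [c for c in t.children if not c.is_leaf]
        assert inner.height == pytest.approx(0.1)
        assert inner.leaf_names() == frozenset({"A", "B"})

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            x = rng.random((n, 4))
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = float(np.abs(x[i] - x[j]).mean())
            t = upgma(DistanceMatrix([f"T{i}" for i in range(n)], d))
            for node in t.internal_nodes():
                for child in node.children:
                    assert child.height <= node.height + 1e-12

    def test_recovers_ultrametric_input_exactly(self):
        # cophenetic distances of the output equal an ultrametric input
        labels = ["A", "B", "C", "D", "E"]
        ab = TreeNode(children=[TreeNode(name="A"), TreeNode(name="B")], height=0.05)
        cd = TreeNode(children=[TreeNode(name="C"), TreeNode(name="D")], height=0.1)
        abcd = TreeNode(children=[ab, cd], height=0.2)
        root = TreeNode(children=[abcd, TreeNode(name="E")], height=0.35)
        dm = root.cophenetic()
        rebuilt = upgma(dm)
        out = rebuilt.cophenetic()
        assert out.labels == dm.labels
        assert np.allclose(out.d, dm.d, atol=1e-12)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            x = rng.random((n, 5))
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = float(min(1.0, np.abs(x[i] - x[j]).sum()))
            t = upgma(DistanceMatrix([f"T{i}" for i in range(n)], d))
            mine = t.cophenetic()
            order = [mine.labels.index(f"T{i}") for i in range(n)]
            Z = linkage(squareform(d), method="average")
            assert np.allclose(
                mine.d[np.ix_(order, order)], squareform(cophenet(Z)), atol=1e-9
            )

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, np.nan], [np.nan, 0]]))


class TestBootstrap:
    def test_default_replicates_is_500(self):
        assert inspect.signature(bootstrap_tree).parameters["n_reps"].default == 500

    def test_zero_variation_gives_full_support(self):
        aln = [(lab, "ACGUACGU" * 5) for lab in "ABCD"]
        t = bootstrap_tree(aln, n_reps=500, seed=9)
        assert all(nd.support == 100.0 for nd in t.internal_nodes())

    def test_supports_reproducible_and_taxon_order_invariant(self):
        from levigene.synthetic import EvolutionConfig, evolve_family, example_tree_6, random_rna

        leaves, _ = evolve_family(
            random_rna(400, 3), EvolutionConfig(tree=example_tree_6(), seed=5)
        )
        t1 = bootstrap_tree(leaves, n_reps=100, seed=4)
        t2 = bootstrap_tree(list(reversed(leaves)), n_reps=100, seed=4)
        s1 = {tuple(sorted(n.leaf_names())): n.support for n in t1.internal_nodes()}
        s2 = {tuple(sorted(n.leaf_names())): n.support for n in t2.internal_nodes()}
        assert s1 == s2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            bootstrap_tree([("a", "ACGU"), ("b", "ACG")], n_reps=2, seed=0)


class TestAlignMulti:
    def test_identical_sequences_align_gap_free(self):
        out = align_multi(["MKVLIVE"] * 3)
        assert all(s == "MKVLIVE" for _, s in out)

    def test_single_indel_is_one_gap_block(self):
        out = align_multi(["MKVLIVESSS", "MKVLESSS"])
        gapped = [s for _, s in out if "-" in s][0]
        assert gapped.count("-") == 2
        # gaps are contiguous
        first = gapped.index("-")
        assert gapped[first : first + 2] == "--"

    def test_column_count_at_least_longest_input(self):
        seqs = ["MKVLIVESSS", "MKVL", "MKESSS"]
        out = align_multi(seqs)
        L = len(out[0][1])
        assert all(len(s) == L for _, s in out)
        assert L >= max(len(s) for s in seqs)

    def test_rows_ungap_to_inputs(self):
        seqs = ["MKVLIVESSS", "MKVLESSS", "MKVLIVESS"]
        out = align_multi(seqs, ["a", "b", "c"])
        back = {lab: s.replace("-", "") for lab, s in out}
        assert back == {"a": seqs[0], "b": seqs[1], "c": seqs[2]}


def test_p_distance_pairwise_deletion():
    aln = [("a", "ACGU-C"), ("b", "ACGAAC")]
    dm = p_distance_matrix(aln)
    # 5 comparable columns, 1 difference
    assert dm.d[0, 1] == pytest.approx(1 / 5)
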