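"""Generator ground truth, determinism and the evolution simulator."""

import math

import numpy as np
import pytest

from levigene.lysis import ScreenConfig, evaluate_candidate
from levigene.comparative import TreeNode, p_distance_matrix, upgma
from levigene.seqio import Region, extract
from levigene.synthetic import (
    EvolutionConfig,
    LYSIS_MODES,
    SyntheticConfig,
    evolve_family,
    example_tree_6,
    generate_genome,
    random_rna,
)


class TestGenerateGenome:
    def test_same_seed_identical_output(self):
        a = generate_genome(seed=42)
        b = generate_genome(seed=42)
        assert a.genome.sequence == b.genome.sequence
        assert a.truth_manifest() == b.truth_manifest()

    def test_different_seeds_differ(self):
        assert (
            generate_genome(seed=1).genome.sequence
            != generate_genome(seed=2).genome.sequence
        )

    def test_default_layout_mirrors_study_genome(self, truth_internal):
        g = truth_internal.genome
        assert g.length == 3405
        lys = truth_internal.lysis.orf
        assert (lys.region.start, lys.region.end) == (2991, 3104)
        assert lys.start_codon == "UUG"
        assert lys.length_aa == 37
        rep = truth_internal.core("replicase").orf
        assert g.length - rep.region.end == 101  # the ~100-nt 3' UTR
        # overlap in a shifted frame, wholly within replicase
        assert rep.region.start <= lys.region.start
        assert lys.region.end <= rep.region.end
        assert lys.frame != rep.frame

    def test_gene_order_and_invariants(self, truth_internal):
        roles = {g.role: g.orf for g in truth_internal.genes}
        assert (
            roles["maturation"].region.start
            < roles["coat"].region.start
            < roles["replicase"].region.start
        )
        for orf in roles.values():
            assert len(orf.region) % 3 == 0
            assert orf.length_aa == len(orf.region) // 3 - 1
            assert "*" not in orf.protein

    @pytest.mark.parametrize("mode", LYSIS_MODES)
    def test_lysis_modes_place_orf_as_named(self, mode):
        truth = generate_genome(SyntheticConfig(lysis_mode=mode), seed=11)
        lys = truth.lysis.orf.region
        coat = truth.core("coat").orf.region
        rep = truth.core("replicase").orf.region
        mat = truth.core("maturation").orf.region
        if mode == "replicase_internal":
            assert rep.start <= lys.start and lys.end <= rep.end
            assert truth.lysis.orf.frame != truth.core("replicase").orf.frame
        elif mode == "coat_replicase_junction":
            assert lys.overlaps(Region(coat.start, rep.start))
            assert truth.lysis.orf.frame != truth.core("coat").orf.frame
        else:
            assert lys.end < mat.start

    @pytest.mark.parametrize("mode", LYSIS_MODES)
    def test_planted_lysis_satisfies_all_four_criteria(self, mode):
        truth = generate_genome(SyntheticConfig(lysis_mode=mode), seed=7)
        cand = evaluate_candidate(truth.genome, truth.lysis.orf, ScreenConfig())
        assert cand.c1_length_ok
        assert cand.c2_tm.has_tm
        assert cand.c3_sd is not None and cand.c3_sd.motif_seq.endswith("GAGG"[-2:])
        assert cand.c3_sd.spacing_nt == 9
        assert cand.c4_start_hairpin.passes

    def test_planted_sd_sequence_is_gagg(self, truth_internal):
        sd = truth_internal.elements.lysis_sd
        assert extract(truth_internal.genome, sd) == "GAGG"

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(genome_length=3000)  # UTR length inconsistent
        with pytest.raises(ValueError):
            SyntheticConfig(lysis_mode="nonsense")


class TestEvolveFamily:
    def test_zero_branch_lengths_copy_root(self):
        tree = TreeNode(
            children=[TreeNode(name="X"), TreeNode(name="Y")], height=0.0
        )
        root = random_rna(120, 1)
        leaves, _ = evolve_family(root, EvolutionConfig(tree=tree, seed=2))
        assert all(s == root for _, s in leaves)

    def test_deterministic_per_seed(self):
        tree = example_tree_6()
        root = random_rna(200, 9)
        a, _ = evolve_family(root, EvolutionConfig(tree=tree, seed=5))
        b, _ = evolve_family(root, EvolutionConfig(tree=tree, seed=5))
        assert a == b

    def test_p_distance_matches_jukes_cantor_expectation(self):
        # two leaves at height h: E[p] = 3/4 (1 - exp(-8h/3))
        h = 0.1
        tree = TreeNode(
            children=[TreeNode(name="X"), TreeNode(name="Y")], height=h
        )
        ps = []
        for rep in range(200):
            leaves, _ = evolve_family(
                random_rna(300, rep), EvolutionConfig(tree=tree, seed=rep)
            )
            ps.append(p_distance_matrix(leaves).d[0, 1])
        expected = 0.75 * (1 - math.exp(-8 * h / 3))
        # Monte-Carlo tolerance: ~4 sigma of the mean of 200 x 300 sites
        assert np.mean(ps) == pytest.approx(expected, abs=0.01)

    def test_low_rate_family_recovers_topology(self):
        leaves, true_tree = evolve_family(
            random_rna(600, 42), EvolutionConfig(tree=example_tree_6(), seed=7)
        )
        t = upgma(p_distance_matrix(leaves))
        assert true_tree.clades() <= t.clades() | {t.leaf_names()}

    def test_indels_change_lengths(self):
        tree = TreeNode(
            children=[TreeNode(name="X"), TreeNode(name="Y")], height=0.2
        )
        leaves, _ = evolve_family(
            random_rna(200, 3),
            EvolutionConfig(tree=tree, indel_rate=0.05, seed=8),
        )
        lengths = {len(s) for _, s in leaves}
        assert len(lengths) > 1 or 200 not in lengths
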