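"""The four lysis-screen criteria and the composite ranking."""

import random

import pytest

from levigene.lysis import (
    KYTE_DOOLITTLE,
    ScreenConfig,
    find_sd,
    predict_tm,
    screen,
    start_hairpin_stability,
)
from levigene.seqio import GenomeRecord, SequenceError


class TestFindSD:
    def test_all_a_context_has_none(self):
        g = GenomeRecord("x", "A" * 60 + "UUG" + "A" * 30)
        assert find_sd(g, 61) is None

    def test_planted_gagg_at_spacing_nine(self):
        # GAGG, nine intervening nt, then the UUG start
        g = GenomeRecord("x", "C" * 20 + "GAGG" + "A" * 9 + "UUG" + "C" * 20)
        sd = find_sd(g, 34)
        assert sd is not None
        assert sd.motif_seq == "GAGG"
        assert sd.spacing_nt == 9
        assert sd.score == 4

    def test_longer_motif_scores_higher(self):
        g1 = GenomeRecord("x", "C" * 20 + "AGGAGG" + "A" * 7 + "UUG" + "C" * 10)
        g2 = GenomeRecord("x", "C" * 22 + "GAGG" + "A" * 7 + "UUG" + "C" * 10)
        sd1 = find_sd(g1, 34)
        sd2 = find_sd(g2, 34)
        assert sd1.spacing_nt == 7
        assert sd1.score == 6 > sd2.score == 4

    def test_score_monotone_in_match_length(self):
        # planting successively longer AGGAGG prefixes never lowers the score
        scores = []
        for k in range(4, 7):
            motif = "AGGAGG"[:k]
            g = GenomeRecord("x", "C" * 24 + motif + "A" * 9 + "UUG" + "C" * 10)
            sd = find_sd(g, 24 + k + 9 + 1)
            scores.append(sd.score)
        assert scores == sorted(scores)

    def test_spacing_outside_window_rejected(self):
        g = GenomeRecord("x", "C" * 20 + "GAGG" + "A" * 20 + "UUG" + "C" * 10)
        sd = find_sd(g, 45)
        assert sd is None or sd.spacing_nt <= 14


class TestPredictTM:
    def test_polyarginine_never_tm(self):
        tm = predict_tm("R" * 40)
        assert not tm.has_tm
        assert tm.mean_hydropathy == pytest.approx(-4.5)

    def test_leucine_block_is_tm(self):
        tm = predict_tm("K" * 10 + "L" * 19 + "K" * 10)
        assert tm.has_tm
        assert tm.mean_hydropathy == pytest.approx(3.8)
        assert (tm.window.start, tm.window.end) == (11, 29)

    def test_matches_brute_force_windows(self):
        random.seed(17)
        aas = list(KYTE_DOOLITTLE)
        for _ in range(40):
            n = random.randint(19, 80)
            prot = "".join(random.choice(aas) for _ in range(n))
            tm = predict_tm(prot)
            means = [
                sum(KYTE_DOOLITTLE[a] for a in prot[s : s + 19]) / 19
                for s in range(n - 18)
            ]
            assert tm.mean_hydropathy == pytest.approx(max(means))

    def test_short_protein_uses_whole_length_window(self):
        tm = predict_tm("L" * 16)
        assert (tm.window.start, tm.window.end) == (1, 16)

    def test_too_short_rejected(self):
        with pytest.raises(SequenceError, match="too short"):
            predict_tm("MKLV")


class TestStartHairpin:
    def test_all_a_window_passes(self):
        g = GenomeRecord("x", "A" * 100)
        res = start_hairpin_stability(g, 50)
        assert res.dg == 0.0
        assert res.passes
        assert res.au_fraction == 1.0

    def test_gc_clamp_fails(self):
        # a strong 10-bp GC hairpin right on the start codon
        stem = "GGCGGCGGCG"
        g = GenomeRecord(
            "x", "A" * 30 + stem + "AACA" + stem[::-1].translate(
                str.maketrans("GC", "CG")
            ) + "A" * 30
        )
        start = 31 + len(stem) + 4  # inside the 3' arm
        res = start_hairpin_stability(g, start)
        assert res.dg < -6.0
        assert not res.passes

    def test_planted_lysis_start_is_weak_and_au_rich(self, truth_internal):
        start = truth_internal.lysis.orf.region.start
        res = start_hairpin_stability(truth_internal.genome, start)
        assert res.passes
        assert res.dg >= -6.0
        assert res.au_fraction > 0.5


class TestScreen:
    def test_acgenome_without_orfs_yields_empty(self):
        g = GenomeRecord("x", "AC" * 300)
        result = screen(g, [])
        assert result.candidates == []

    def test_planted_lysis_is_rank_one(self, truth_internal):
        from levigene.orfs import assign_core_genes, find_orfs

        g = truth_internal.genome
        ann = assign_core_genes(find_orfs(g), g)
        res = screen(g, ann)
        top = res.candidates[0]
        lys = truth_internal.lysis.orf.region
        assert (top.orf.region.start, top.orf.region.end) == (lys.start, lys.end)
        assert top.orf.start_codon == "UUG"
        assert top.c1_length_ok
        assert top.c2_tm.has_tm
        assert top.c3_sd is not None and top.c3_sd.spacing_nt == 9
        assert top.c4_start_hairpin.passes
        assert res.location_report["candidate_within_replicase"] is True

    def test_ranks_are_unique_and_sorted(self, truth_internal):
        from levigene.orfs import assign_core_genes, find_orfs

        g = truth_internal.genome
        ann = assign_core_genes(find_orfs(g), g)
        res = screen(g, ann)
        ranks = [c.rank for c in res.candidates]
        assert ranks == list(range(1, len(ranks) + 1))
        scores = [c.composite_score for c in res.candidates]
        assert scores == sorted(scores, reverse=True)

    def test_core_gene_truncations_excluded(self, truth_internal):
        from levigene.orfs import assign_core_genes, find_orfs

        g = truth_internal.genome
        ann = assign_core_genes(find_orfs(g), g)
        res = screen(g, ann)
        core_stops = {
            (a.orf.region.end, a.orf.frame)
            for a in ann
            if a.role in ("maturation", "coat", "replicase")
        }
        for c in res.candidates:
            assert (c.orf.region.end, c.orf.frame) not in core_stops

    def test_junction_mode_probes_report_location(self, truth_junction):
        from levigene.orfs import assign_core_genes, find_orfs

        g = truth_junction.genome
        ann = assign_core_genes(find_orfs(g), g)
        res = screen(g, ann)
        assert res.location_report["candidate_at_coat_replicase_junction"] is True
        top = res.candidates[0]
        lys = truth_junction.lysis.orf.region
        assert (top.orf.region.start, top.orf.region.end) == (lys.start, lys.end)
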