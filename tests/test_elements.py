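"""Detectors for the conserved structural elements, on planted truth."""

import pytest

from levigene.seqio import GenomeRecord, Region, extract, reverse_complement
from levigene.structure import (
    analyze_3utr,
    detect_five_prime_hairpin,
    detect_operator,
    pseudoknot_partner_search,
)


class TestFivePrimeHairpin:
    def test_all_a_genome_has_none(self):
        g = GenomeRecord("x", "A" * 120)
        assert detect_five_prime_hairpin(g) is None

    def test_planted_gc_hairpin_detected_at_coordinates(self, truth_internal):
        hp = detect_five_prime_hairpin(truth_internal.genome)
        planted = truth_internal.elements.five_prime_hairpin
        assert hp is not None
        assert (hp.span.start, hp.span.end) == (planted.start, planted.end)
        assert hp.n_bp == 8

    def test_window_cap(self, truth_internal):
        with pytest.raises(ValueError):
            detect_five_prime_hairpin(truth_internal.genome, window_nt=80)


class TestOperator:
    def test_unpairable_window_returns_none(self):
        g = GenomeRecord("x", "AC" * 200)
        rep = 200
        op = detect_operator(g, rep)
        assert op.hairpin is None
        assert op.loop_adenine_minus4 is None

    def test_planted_operator_diagnostics(self, truth_internal):
        rep_start = truth_internal.core("replicase").orf.region.start
        op = detect_operator(truth_internal.genome, rep_start)
        planted = truth_internal.elements.operator_span
        assert op.hairpin is not None
        # detected hairpin covers the planted stem-loop and the start codon
        assert op.hairpin.span.start <= planted.start
        assert op.hairpin.span.end >= planted.end
        assert op.loop_adenine_minus4 is True
        assert op.unpaired_purine_in_stem is True
        # the -4 position really is an adenine in the genome
        assert extract(
            truth_internal.genome, Region(rep_start - 4, rep_start - 4)
        ) == "A"


class TestThreePrimeUTR:
    def test_short_utr_rejected(self):
        g = GenomeRecord("x", "A" * 100)
        with pytest.raises(ValueError, match="shorter"):
            analyze_3utr(g, replicase_end=90)

    def test_planted_domain_recovered(self, truth_internal):
        rep_end = truth_internal.core("replicase").orf.region.end
        utr = analyze_3utr(truth_internal.genome, rep_end)
        el = truth_internal.elements
        # ld IX closes the domain at the planted arms
        assert utr.ld is not None
        assert (utr.ld.arm5.start, utr.ld.arm5.end) == (
            el.ld_arm5.start,
            el.ld_arm5.end,
        )
        assert (utr.ld.arm3.start, utr.ld.arm3.end) == (
            el.ld_arm3.start,
            el.ld_arm3.end,
        )
        assert utr.ld.n_bp == 6
        # four U-hairpins, labeled U1 (3'-terminal) .. U4, at planted spans
        got = {
            h.label: (h.span.start, h.span.end)
            for h in utr.hairpins
            if h.label and h.label.startswith("U")
        }
        assert got == {
            k: (v.start, v.end) for k, v in el.utr_hairpins.items()
        }
        # the U1 loop carries the conserved pseudoknot core
        assert utr.u1_loop_seq == "AUUGCUAUG"
        assert "UUGCU" in utr.u1_loop_seq
        # V-like unpaired linker between U2 and U1, no adenines
        assert utr.v_like_unpaired is not None
        linker = extract(truth_internal.genome, utr.v_like_unpaired)
        assert linker == "UUUUGU"
        assert "A" not in linker

    def test_au_only_utr_gives_no_ld(self):
        # A-only tail cannot pair at all
        g = GenomeRecord("x", "G" * 200 + "A" * 80)
        utr = analyze_3utr(g, replicase_end=200)
        assert utr.ld is None


def brute_force_partner_scan(genome, loop, min_bp, band, allow_gu):
    """Naive all-windows scan used as the oracle."""
    loop_seq = extract(genome, loop)
    near, far = band
    hits = set()
    for length in range(min_bp, len(loop_seq) + 1):
        for off in range(0, len(loop_seq) - length + 1):
            target = reverse_complement(loop_seq[off : off + length])
            if allow_gu:
                continue  # oracle covers WC-only mode
            for p_end in range(loop.start - near, loop.start - far - 1, -1):
                p_start = p_end - length + 1
                if p_start < 1:
                    continue
                if genome.sequence[p_start - 1 : p_end] == target:
                    hits.add((p_start, p_end))
    # keep only maximal windows
    maximal = {
        (s, e)
        for (s, e) in hits
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for (s2, e2) in hits)
    }
    return maximal


class TestPseudoknotSearch:
    def test_empty_when_no_complement_in_band(self):
        g = GenomeRecord("x", "C" * 1500 + "UUGCU" + "C" * 20)
        loop = Region(1501, 1505)
        assert pseudoknot_partner_search(g, loop, 5, (1000, 1400)) == []

    def test_planted_partner_at_1215(self, truth_internal):
        el = truth_internal.elements
        hits = pseudoknot_partner_search(truth_internal.genome, el.u1_loop)
        assert len(hits) == 1
        top = hits[0]
        assert (top.partner_region.start, top.partner_region.end) == (
            el.pseudoknot_partner.start,
            el.pseudoknot_partner.end,
        )
        assert top.partner_seq == "AGCAA"
        assert top.distance_nt == 1215
        assert top.n_bp == 5

    def test_matches_naive_scan(self, truth_internal):
        g = truth_internal.genome
        loop = truth_internal.elements.u1_loop
        got = {
            (h.partner_region.start, h.partner_region.end)
            for h in pseudoknot_partner_search(g, loop, 5, (500, 1400))
        }
        want = brute_force_partner_scan(g, loop, 5, (500, 1400), allow_gu=False)
        assert got == want

    def test_gu_mode_is_superset(self, truth_internal):
        g = truth_internal.genome
        loop = truth_internal.elements.u1_loop
        wc = pseudoknot_partner_search(g, loop, 5, (1000, 1400), allow_gu=False)
        gu = pseudoknot_partner_search(g, loop, 5, (1000, 1400), allow_gu=True)
        assert len(gu) >= len(wc)
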