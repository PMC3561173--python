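"""Synthetic levivirus genomes with fully known ground truth.

The generator emits positive-sense ssRNA genomes with the canonical
maturation/coat/replicase architecture, a planted short lysis ORF in one of
the three layouts observed across the family (overlapping the
coat/replicase junction, buried inside replicase in a shifted frame, or 5'
of maturation), and the conserved structural elements every detector in
this package looks for: a GC-rich 5'-terminal hairpin, an operator hairpin
with the loop adenine at -4 and a bulged purine, a 3'-terminal domain of
four hairpins U4..U1 closed by the long-distance interaction ld IX with an
unpaired UUUUGU linker in place of hairpin V, and an AGCAA pseudoknot
partner a configurable distance (default 1215 nt) upstream of the U1-loop
UUGCU.

The default configuration mirrors the dimensions of the smallest known
genome of the family: 3405 nt total, lysis ORF at 2991-3104 (37 codons,
UUG start, GAGG Shine-Dalgarno at 9-nt spacing), replicase ending at 3304
so the 3' UTR is 101 nt and the replicase frame differs from the lysis
frame as a frame-shifted overlap requires.

Generation is codon-level: planted elements are written first and locked;
gene codons are then sampled from the synonymous sets of random proteins
subject to the locked positions; finally scrub passes remove generation
artifacts (spurious screen-length ORFs, competing pseudoknot matches in
the search band, replicase-tail complementarity to the 3' terminus) via
synonymous codon swaps so the planted truth is uniquely recoverable.
Everything is deterministic per (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .comparative import TreeNode
from .orfs import GeneAnnotation, OrfCall, find_orfs
from .seqio import GenomeRecord, Region, extract, reverse_complement, translate
from .structure import fold_mfe
from .lysis import ScreenConfig, evaluate_candidate

_T11 = CodonTable.unambiguous_rna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_T11.forward_table)
AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _a in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_a, []).append(_c)
STOPS = ("UAA", "UAG", "UGA")
_STARTS = ("AUG", "GUG", "UUG")
AA20 = sorted(AA_TO_CODONS)

LYSIS_MODES = ("coat_replicase_junction", "replicase_internal", "five_prime")

# residue classes used when composing the planted lysis protein
_AU_RICH_CODONS = ["AAA", "AAU", "UAU", "AUU", "AUA", "ACA", "AAC"]
_HYDROPHOBIC = {"L", "I", "V", "F"}
_MIXED_AA = ["K", "N", "S", "T", "A", "G", "R", "Q"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Genome layout; defaults mirror the smallest known levivirus genome."""

    genome_length: int = 3405
    lysis_mode: str = "replicase_internal"
    maturation: tuple[int, int] = (62, 1270)
    maturation_start_five_prime_mode: int = 170
    coat: tuple[int, int] = (1280, 1669)
    replicase: tuple[int, int] = (1703, 3304)
    lysis_regions: dict = field(
        default_factory=lambda: {
            "replicase_internal": (2991, 3104),
            "coat_replicase_junction": (1573, 1686),
            "five_prime": (44, 157),
        }
    )
    sd_spacing_nt: int = 9  # nt strictly between GAGG and the start codon
    pseudoknot_distance_nt: int = 1215  # U1-loop 5' start minus partner 3' end

    def __post_init__(self) -> None:
        if self.lysis_mode not in LYSIS_MODES:
            raise ValueError(f"unknown lysis_mode {self.lysis_mode!r}")
        utr3 = self.genome_length - self.replicase[1]
        if utr3 != 101:
            raise ValueError(
                "3' UTR must be 101 nt for the fixed element layout "
                f"(got {utr3})"
            )
        lys = self.lysis_regions[self.lysis_mode]
        if (lys[1] - lys[0] + 1) % 3 != 0:
            raise ValueError("lysis region length must be a multiple of 3")
        if self.lysis_mode == "replicase_internal":
            if not (self.replicase[0] <= lys[0] and lys[1] <= self.replicase[1]):
                raise ValueError("internal lysis ORF must lie within replicase")
            if (lys[0] - 1) % 3 == (self.replicase[0] - 1) % 3:
                raise ValueError("internal lysis ORF must use a shifted frame")

    @property
    def utr3_region(self) -> Region:
        return Region(self.replicase[1] + 1, self.genome_length)


@dataclass(frozen=True)
class PlantedElements:
    five_prime_hairpin: Region
    operator_span: Region
    operator_loop: Region
    utr_hairpins: dict[str, Region]  # label -> full span
    utr_hairpin_loops: dict[str, Region]
    ld_arm5: Region
    ld_arm3: Region
    v_linker: Region
    u1_loop: Region
    pseudoknot_partner: Region
    lysis_sd: Region


@dataclass(frozen=True)
class SyntheticTruth:
    genome: GenomeRecord
    genes: list[GeneAnnotation]
    lysis_mode: str
    elements: PlantedElements
    seed: int
    config: SyntheticConfig

    @property
    def lysis(self) -> GeneAnnotation:
        return next(g for g in self.genes if g.role == "lysis")

    def core(self, role: str) -> GeneAnnotation:
        return next(g for g in self.genes if g.role == role)

    def truth_manifest(self) -> dict:
        return {
            "id": self.genome.id,
            "seed": self.seed,
            "lysis_mode": self.lysis_mode,
            "genome_length": self.genome.length,
            "genes": [
                {
                    "role": g.role,
                    "start": g.orf.region.start,
                    "end": g.orf.region.end,
                    "start_codon": g.orf.start_codon,
                    "length_aa": g.orf.length_aa,
                }
                for g in self.genes
            ],
            "elements": {
                "five_prime_hairpin": _reg(self.elements.five_prime_hairpin),
                "operator_span": _reg(self.elements.operator_span),
                "u1_loop": _reg(self.elements.u1_loop),
                "ld_arm5": _reg(self.elements.ld_arm5),
                "ld_arm3": _reg(self.elements.ld_arm3),
                "v_linker": _reg(self.elements.v_linker),
                "pseudoknot_partner": _reg(self.elements.pseudoknot_partner),
                "lysis_sd": _reg(self.elements.lysis_sd),
                "utr_hairpins": {
                    k: _reg(v) for k, v in self.elements.utr_hairpins.items()
                },
            },
        }


def _reg(r: Region) -> list[int]:
    return [r.start, r.end]


def _rc(s: str) -> str:
    return reverse_complement(s)


# fixed planted sequences ----------------------------------------------------

_FP_STEM5 = "GCGGCGGC"
_FP_LOOP = "AACA"

_OP_STEM3 = "AUGGCGCC"  # starts with the replicase AUG
_OP_LOOP = "AACAACA"  # position -4 relative to the start codon is an A
_OP_BULGE_AT = 4  # a bulged A is inserted mid-helix in the 5' arm

_LD5 = "GGCGUG"
_UTR_HAIRPINS = {
    # label -> (stem5, loop)
    "U4": ("GCAGGC", "AAAA"),
    "U3": ("GGUCGC", "AAAA"),
    "U2": ("GCUGGC", "AAAA"),
    "U1": ("GGCAGG", "AUUGCUAUG"),
}
_V_LINKER = "UUUUGU"
_UTR_SPACER = "AAA"
# the spacer 5' of U2 and the pre-terminal spacer flank the U-rich linker /
# U1 stem; C-based spacers cannot pair with it and extend the planted stems
_U2_SPACER = "CCC"
_PRETERM_SPACER = "CUCAA"


class _Builder:
    def __init__(self, config: SyntheticConfig, seed: int):
        self.cfg = config
        self.seed = seed
        self.rng = np.random.default_rng([seed & 0x7FFFFFFF, 977])
        n = config.genome_length
        self.g: list[Optional[str]] = [None] * (n + 1)  # 1-based
        self.locked = [False] * (n + 1)
        self.elements: dict = {}

    # -- primitives ---------------------------------------------------------

    def place(self, pos: int, s: str, lock: bool = True) -> None:
        for k, ch in enumerate(s):
            p = pos + k
            if self.locked[p] and self.g[p] != ch:
                raise ValueError(f"position {p} already locked to {self.g[p]}")
            self.g[p] = ch
            if lock:
                self.locked[p] = True

    def seq(self, start: int, end: int) -> str:
        return "".join(self.g[start : end + 1])

    def pattern(self, start: int) -> str:
        """3-nt pattern at `start` with '.' for free positions."""
        return "".join(
            (self.g[p] if self.locked[p] and self.g[p] else ".")
            for p in range(start, start + 3)
        )

    # -- element planting ---------------------------------------------------

    def plant_five_prime_hairpin(self) -> None:
        s = _FP_STEM5 + _FP_LOOP + _rc(_FP_STEM5)
        self.place(3, s)
        self.elements["five_prime_hairpin"] = Region(3, 2 + len(s))

    def plant_operator(self) -> None:
        rep_start = self.cfg.replicase[0]
        stem3_start = rep_start  # stem3 begins with the AUG
        loop_start = stem3_start - len(_OP_LOOP)
        stem5 = _rc(_OP_STEM3)
        stem5 = stem5[:_OP_BULGE_AT] + "A" + stem5[_OP_BULGE_AT:]
        stem5_start = loop_start - len(stem5)
        self.place(stem5_start, stem5)
        self.place(loop_start, _OP_LOOP)
        self.place(stem3_start, _OP_STEM3)
        self.elements["operator_span"] = Region(
            stem5_start, stem3_start + len(_OP_STEM3) - 1
        )
        self.elements["operator_loop"] = Region(loop_start, stem3_start - 1)

    def plant_utr(self) -> None:
        cfg = self.cfg
        cursor = cfg.replicase[1] + 1
        self.place(cursor, _LD5)
        self.elements["ld_arm5"] = Region(cursor, cursor + 5)
        cursor += 6
        self.place(cursor, _UTR_SPACER)
        cursor += 3
        spans: dict[str, Region] = {}
        loops: dict[str, Region] = {}
        for label in ("U4", "U3", "U2"):
            stem5, loop = _UTR_HAIRPINS[label]
            s = stem5 + loop + _rc(stem5)
            self.place(cursor, s)
            spans[label] = Region(cursor, cursor + len(s) - 1)
            loops[label] = Region(
                cursor + len(stem5), cursor + len(stem5) + len(loop) - 1
            )
            cursor += len(s)
            if label == "U3":
                self.place(cursor, _U2_SPACER)
                cursor += 3
            elif label != "U2":
                self.place(cursor, _UTR_SPACER)
                cursor += 3
        self.place(cursor, _V_LINKER)
        self.elements["v_linker"] = Region(cursor, cursor + len(_V_LINKER) - 1)
        cursor += len(_V_LINKER)
        stem5, loop = _UTR_HAIRPINS["U1"]
        s = stem5 + loop + _rc(stem5)
        self.place(cursor, s)
        spans["U1"] = Region(cursor, cursor + len(s) - 1)
        loops["U1"] = Region(
            cursor + len(stem5), cursor + len(stem5) + len(loop) - 1
        )
        cursor += len(s)
        self.place(cursor, _PRETERM_SPACER)
        cursor += len(_PRETERM_SPACER)
        self.place(cursor, _rc(_LD5))
        self.elements["ld_arm3"] = Region(cursor, cursor + 5)
        assert cursor + 5 == self.cfg.genome_length
        self.elements["utr_hairpins"] = spans
        self.elements["utr_hairpin_loops"] = loops
        self.elements["u1_loop"] = loops["U1"]

    def plant_pseudoknot_partner(self) -> None:
        # U1 loop is AUUGCUAUG; its UUGCU core pairs AGCAA upstream.
        loop = self.elements["u1_loop"]
        partner_end = loop.start - self.cfg.pseudoknot_distance_nt
        partner = _rc("UUGCU")  # AGCAA
        self.place(partner_end - len(partner) + 1, partner)
        self.elements["pseudoknot_partner"] = Region(
            partner_end - len(partner) + 1, partner_end
        )

    # -- lysis segment ------------------------------------------------------

    def plant_lysis(self) -> None:
        cfg = self.cfg
        lys_start, lys_end = cfg.lysis_regions[cfg.lysis_mode]
        n_codons = (lys_end - lys_start + 1) // 3  # incl. stop
        n_aa = n_codons - 1
        sd_end = lys_start - 1 - cfg.sd_spacing_nt
        sd_start = sd_end - 3  # GAGG
        # host gene whose frame constrains the overlap
        host = None
        if cfg.lysis_mode == "replicase_internal":
            host = cfg.replicase
        elif cfg.lysis_mode == "coat_replicase_junction":
            host = cfg.coat
        host_stop: Optional[int] = None
        if host is not None and lys_end > host[1] - 2 >= lys_start:
            host_stop = host[1] - 2  # host stop codon start inside lysis
        # frame of the next gene downstream of the segment: a start codon in
        # that frame inside the segment would extend the downstream gene
        # 5'-ward and shift its annotated coordinates
        # (in five_prime mode the lysis ORF shares the maturation frame, so
        # its own stop codon already blocks any upstream extension)
        if cfg.lysis_mode == "coat_replicase_junction":
            guard_frame = (cfg.replicase[0] - 1) % 3
        else:
            guard_frame = None

        forced: dict[int, str] = {}
        # spacer ends with a lysis-frame stop guarding against upstream
        # in-frame extensions of the planted ORF
        spacer_stop_start = lys_start - 3
        for attempt in range(400):
            rng = np.random.default_rng(
                [self.seed & 0x7FFFFFFF, 1549, attempt]
            )
            forced.clear()
            if host_stop is not None:
                stop = STOPS[rng.integers(0, 3)]
                for k, ch in enumerate(stop):
                    forced[host_stop + k] = ch
            segment: dict[int, str] = {}

            def put(pos: int, s: str) -> bool:
                for k, ch in enumerate(s):
                    if forced.get(pos + k, ch) != ch:
                        return False
                    segment[pos + k] = ch
                return True

            ok = put(sd_start, "GAGG")
            # spacer: AU-rich filler then the guard stop
            for p in range(sd_end + 1, spacer_stop_start):
                ch = forced.get(p, "AU"[rng.integers(0, 2)])
                segment[p] = ch
            ok = ok and put(spacer_stop_start, "UAA")
            # guard spacer codons against being start codons
            sp = "".join(segment[p] for p in range(sd_end + 1, spacer_stop_start))
            if any(sp[i : i + 3] in _STARTS for i in range(0, len(sp) - 2, 3)):
                continue
            ok = ok and put(lys_start, "UUG")
            if not ok:
                continue
            # host-frame codons must stay sense (except the forced host
            # stop); the check is applied locally as each lysis codon is
            # chosen, because every hydrophobic codon has a middle U and a
            # global accept/reject over 19 stop-prone junctions never lands
            def host_ok_through(hi: int) -> bool:
                if host is not None:
                    for cpos in range(host[0], host[1] + 1, 3):
                        if cpos < min(segment) or cpos + 2 > hi:
                            continue
                        codon = "".join(
                            segment.get(cpos + k, "?") for k in range(3)
                        )
                        if "?" in codon:
                            continue
                        if codon in STOPS and cpos != host_stop:
                            return False
                        if cpos == host_stop and codon not in STOPS:
                            return False
                if guard_frame is not None:
                    lo = min(segment)
                    first = lo + (guard_frame - lo + 1) % 3
                    for p in range(first, hi - 1, 3):
                        codon = "".join(segment.get(p + k, "?") for k in range(3))
                        if codon in _STARTS:
                            return False
                return True

            if not host_ok_through(lys_start + 2):
                continue
            # codons for residues 2..n_aa, then the stop codon
            good = True
            for idx in range(1, n_codons):
                pos = lys_start + 3 * idx
                pat = [forced.get(pos + k) for k in range(3)]
                if idx == n_codons - 1:
                    pool = list(STOPS)
                elif 8 <= idx <= 26:
                    pool = [
                        c
                        for a in sorted(_HYDROPHOBIC)
                        for c in AA_TO_CODONS[a]
                        if c not in _STARTS
                    ]
                elif idx <= 7:
                    pool = list(_AU_RICH_CODONS)
                else:
                    pool = [
                        c
                        for a in _MIXED_AA
                        for c in AA_TO_CODONS[a]
                        if c not in _STARTS
                    ]
                pool = [
                    c
                    for c in pool
                    if all(pat[k] is None or pat[k] == c[k] for k in range(3))
                ]
                if not pool and idx != n_codons - 1:
                    # forced host-frame positions may demand residues outside
                    # the composition classes; any sense codon is acceptable
                    pool = [
                        c
                        for c in CODON_TO_AA
                        if c not in _STARTS
                        and all(pat[k] is None or pat[k] == c[k] for k in range(3))
                    ]
                pool = list(pool)
                rng.shuffle(pool)
                placed = False
                for codon in pool:
                    for k, ch in enumerate(codon):
                        segment[pos + k] = ch
                    if host_ok_through(pos + 2):
                        placed = True
                        break
                if not placed:
                    for k in range(3):
                        segment.pop(pos + k, None)
                    good = False
                    break
            if not good:
                continue
            if not host_ok_through(max(segment)):
                continue
            # weak, AU-rich start-codon hairpin: fold the 30-nt window
            lo = lys_start - 13
            window = "".join(segment[p] for p in range(lo, lo + 30))
            if fold_mfe(window).energy < -5.0:
                continue
            # commit
            for p in sorted(segment):
                self.place(p, segment[p])
            self.elements["lysis_sd"] = Region(sd_start, sd_end)
            self.elements["lysis_region"] = Region(lys_start, lys_end)
            return
        raise RuntimeError("could not plant a valid lysis segment")

    # -- gene fill ----------------------------------------------------------

    def fill_gene(self, region: tuple[int, int], salt: int) -> None:
        start, end = region
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, 3301, salt])
        sense = [c for c in CODON_TO_AA]
        for cpos in range(start, end + 1, 3):
            pat = self.pattern(cpos)
            if "." not in pat:
                continue  # fully locked (planted)
            is_stop_codon = cpos == end - 2
            if is_stop_codon:
                pool = [s for s in STOPS if _match(s, pat)]
            elif cpos == start:
                pool = ["AUG"] if _match("AUG", pat) else []
            else:
                pool = [c for c in sense if _match(c, pat)]
            if not pool:
                raise ValueError(
                    f"no codon fits locked pattern {pat!r} at {cpos}"
                )
            codon = pool[rng.integers(0, len(pool))]
            for k, ch in enumerate(codon):
                p = cpos + k
                if not self.locked[p]:
                    self.g[p] = ch

    def fill_filler(self) -> None:
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, 4409])
        for p in range(1, self.cfg.genome_length + 1):
            if self.g[p] is None:
                self.g[p] = "A" if rng.random() < 0.7 else "C"

    # -- scrub passes -------------------------------------------------------

    def _gene_regions(self) -> list[tuple[int, int]]:
        cfg = self.cfg
        mat = (
            (cfg.maturation_start_five_prime_mode, cfg.maturation[1])
            if cfg.lysis_mode == "five_prime"
            else cfg.maturation
        )
        return [mat, cfg.coat, cfg.replicase]

    def _protected_stops(self) -> set[tuple[int, int]]:
        lys = self.elements["lysis_region"]
        keep = {(lys.end, (lys.start - 1) % 3)}
        for r in self._gene_regions():
            keep.add((r[1], (r[0] - 1) % 3))
        return keep

    def _swap_codon(self, cpos: int, rng, accept) -> bool:
        """Try synonymous alternatives of the (fully unlocked) codon at
        ``cpos``; commit the first one `accept` likes."""
        if any(self.locked[cpos + k] for k in range(3)):
            return False
        current = self.seq(cpos, cpos + 2)
        aa = CODON_TO_AA.get(current)
        if aa is None:
            return False
        alts = [c for c in AA_TO_CODONS[aa] if c != current]
        rng.shuffle(alts)
        for alt in alts:
            for k, ch in enumerate(alt):
                self.g[cpos + k] = ch
            if accept():
                return True
        for k, ch in enumerate(current):
            self.g[cpos + k] = ch
        return False

    def _codons_covering(self, lo: int, hi: int) -> list[int]:
        out = []
        for gs, ge in self._gene_regions():
            if hi < gs or lo > ge:
                continue
            first = gs + max(0, (lo - gs) // 3) * 3
            for cpos in range(first, min(ge - 2, hi) + 1, 3):
                if cpos + 2 >= lo:
                    out.append(cpos)
        return out

    def scrub_spurious_orfs(self) -> None:
        """Break non-planted ORFs long enough to enter the lysis screen."""
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, 5087])
        protected = self._protected_stops()
        lys = self.elements["lysis_region"]
        for _ in range(25):
            genome = GenomeRecord("tmp", self.seq(1, self.cfg.genome_length))
            targets = [
                o
                for o in find_orfs(genome, min_length_aa=34)
                if (o.region.end, o.frame) not in protected and o.primary
            ]
            if not targets:
                return
            changed = False
            for orf in targets:
                frame = orf.frame
                # try to introduce an in-frame stop inside the ORF
                def try_positions() -> bool:
                    cands = self._codons_covering(
                        orf.region.start, orf.region.end - 3
                    )
                    rng.shuffle(cands)
                    for cpos in cands:

                        def makes_stop() -> bool:
                            for q in range(max(1, cpos - 2), cpos + 3):
                                if (q - 1) % 3 != frame:
                                    continue
                                if not (orf.region.start <= q <= orf.region.end - 5):
                                    continue
                                if self.seq(q, q + 2) in STOPS:
                                    return True
                            return False

                        if self._swap_codon(cpos, rng, makes_stop):
                            return True
                    return False

                if try_positions():
                    changed = True
                    continue
                # fall back: destroy the start codon
                for cpos in self._codons_covering(
                    orf.region.start, orf.region.start + 2
                ):
                    def kills_start() -> bool:
                        return self.seq(orf.region.start, orf.region.start + 2) not in _STARTS

                    if self._swap_codon(cpos, rng, kills_start):
                        changed = True
                        break
                else:
                    # ORF in pure filler: overwrite an in-frame codon with a stop
                    for q in range(orf.region.start + 3, orf.region.end - 5, 3):
                        if lys.start <= q <= lys.end:
                            continue
                        if not any(self.locked[q + k] for k in range(3)) and not self._codons_covering(q, q + 2):
                            self.place(q, "UAA", lock=False)
                            changed = True
                            break
            if not changed:
                return

    def scrub_pseudoknot_band(self) -> None:
        """Leave exactly one complementary window in the search band."""
        from .structure import pseudoknot_partner_search

        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, 6211])
        loop = self.elements["u1_loop"]
        planted = self.elements["pseudoknot_partner"]
        for _ in range(30):
            genome = GenomeRecord("tmp", self.seq(1, self.cfg.genome_length))
            extras = [
                c
                for c in pseudoknot_partner_search(genome, loop, min_bp=5)
                if not (
                    c.partner_region.start >= planted.start
                    and c.partner_region.end <= planted.end
                )
            ]
            if not extras:
                return
            fixed_any = False
            for cand in extras:
                lo, hi = cand.partner_region.start, cand.partner_region.end
                free = [
                    p for p in range(lo, hi + 1) if not self.locked[p]
                ]
                if not free:
                    continue

                def broken() -> bool:
                    return self.seq(lo, hi) != cand.partner_seq

                done = False
                for cpos in self._codons_covering(lo, hi):
                    if self._swap_codon(cpos, rng, broken):
                        done = fixed_any = True
                        break
                if not done:
                    for p in free:
                        old = self.g[p]
                        self.g[p] = "C" if old != "C" else "A"
                        fixed_any = True
                        break
            if not fixed_any:
                return

    def scrub_tail_complementarity(self) -> None:
        """Keep the replicase tail from out-pairing ld IX at the terminus."""
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, 7121])
        n = self.cfg.genome_length
        # both ld IX arms must find each other, not the (random) tail
        arms = [self.seq(n - 9, n), self.seq(self.cfg.replicase[1] + 1,
                                             self.cfg.replicase[1] + 10)]
        tail_lo, tail_hi = self.cfg.replicase[1] - 59, self.cfg.replicase[1]
        for _ in range(30):
            hit = None
            for arm in arms:
                for L in range(6, 3, -1):
                    for t0 in range(0, len(arm) - L + 1):
                        target = _rc(arm[t0 : t0 + L])
                        hay = self.seq(tail_lo, tail_hi)
                        k = hay.find(target)
                        if k >= 0:
                            hit = (tail_lo + k, tail_lo + k + L - 1)
                            break
                    if hit:
                        break
                if hit:
                    break
            if hit is None:
                return
            lo, hi = hit
            changed = False
            for cpos in self._codons_covering(lo, hi):
                before = self.seq(lo, hi)

                def differs() -> bool:
                    return self.seq(lo, hi) != before

                if self._swap_codon(cpos, rng, differs):
                    changed = True
                    break
            if not changed:
                return


    def scrub_ld_fold(self) -> None:
        """Refold the 3' domain and break any tail helix that invades the
        planted UTR pairing (wobble helices escape string matching)."""
        from .structure import analyze_3utr

        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, 8221])
        utr_start = self.cfg.replicase[1] + 1
        n = self.cfg.genome_length
        ld5 = range(utr_start, utr_start + 6)
        ld3 = range(n - 5, n + 1)
        for _ in range(8):
            genome = GenomeRecord("tmp", self.seq(1, n))
            utr = analyze_3utr(genome, self.cfg.replicase[1])
            delta = utr.window.start - 1
            pm = utr.structure.pair_map
            pairs = {
                (min(i, j) + 1 + delta, max(i, j) + 1 + delta)
                for i, j in pm.items()
            }
            want = {(a, b) for a, b in zip(ld5, reversed(ld3))}
            if want <= pairs:
                return
            # tail positions paired into the planted UTR
            offenders = sorted(
                {
                    p
                    for a, b in pairs
                    for p in (a, b)
                    if p < utr_start and (a >= utr_start or b >= utr_start)
                }
            )
            changed = False
            for p in offenders:
                for cpos in self._codons_covering(p, p):
                    before = self.seq(cpos, cpos + 2)

                    def differs() -> bool:
                        return self.seq(cpos, cpos + 2) != before

                    if self._swap_codon(cpos, rng, differs):
                        changed = True
                        break
                if changed:
                    break
            if not changed:
                return

    def scrub_operator_fold(self) -> None:
        """Ensure the operator window folds to the planted hairpin with both
        diagnostics; swap free replicase codons in the window otherwise."""
        from .structure import detect_operator

        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, 8377])
        rep_start = self.cfg.replicase[0]
        span = self.elements["operator_span"]
        for _ in range(8):
            genome = GenomeRecord("tmp", self.seq(1, self.cfg.genome_length))
            op = detect_operator(genome, rep_start)
            ok = (
                op.hairpin is not None
                and op.hairpin.span.start <= span.start
                and span.end <= op.hairpin.span.end
                and op.loop_adenine_minus4
                and op.unpaired_purine_in_stem
            )
            if ok:
                return
            changed = False
            for cpos in self._codons_covering(span.end + 1, op.window.end):
                before = self.seq(cpos, cpos + 2)

                def differs() -> bool:
                    return self.seq(cpos, cpos + 2) != before

                if self._swap_codon(cpos, rng, differs):
                    changed = True
                    break
            if not changed:
                return


def _match(codon: str, pattern: str) -> bool:
    return all(p == "." or p == c for p, c in zip(pattern, codon))


def generate_genome(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    verify: bool = False,
) -> SyntheticTruth:
    """Generate one synthetic genome with planted ground truth.

    Deterministic: identical (config, seed) give byte-identical genomes.
    With ``verify=True`` the planted lysis ORF is re-checked against all
    four screen criteria and the genome is regenerated with a fresh salt on
    failure (the check folds RNA windows, so it costs a little time).
    """
    cfg = config or SyntheticConfig()
    for salt in range(8):
        salted = seed if salt == 0 else (seed + 104729 * salt) & 0x7FFFFFFF
        b = _Builder(cfg, salted)
        b.plant_five_prime_hairpin()
        b.plant_operator()
        b.plant_utr()
        b.plant_pseudoknot_partner()
        b.plant_lysis()
        mat = (
            (cfg.maturation_start_five_prime_mode, cfg.maturation[1])
            if cfg.lysis_mode == "five_prime"
            else cfg.maturation
        )
        for i, gene in enumerate((mat, cfg.coat, cfg.replicase)):
            b.fill_gene(gene, salt=i)
        # maturation Shine-Dalgarno (cosmetic realism; junction/internal only)
        if cfg.lysis_mode != "five_prime":
            sd_end = mat[0] - 1 - cfg.sd_spacing_nt
            try:
                b.place(sd_end - 3, "GAGG", lock=False)
            except ValueError:
                pass
        b.fill_filler()
        b.scrub_spurious_orfs()
        b.scrub_pseudoknot_band()
        b.scrub_tail_complementarity()
        b.scrub_ld_fold()
        b.scrub_operator_fold()
        b.scrub_spurious_orfs()
        b.scrub_pseudoknot_band()

        genome = GenomeRecord(
            f"synthetic_levivirus_seed{seed}",
            b.seq(1, cfg.genome_length),
            description=f"synthetic levivirus genome, lysis_mode={cfg.lysis_mode}",
        )
        lys = b.elements["lysis_region"]
        genes = []
        for role, (s, e) in (
            ("maturation", mat),
            ("coat", cfg.coat),
            ("replicase", cfg.replicase),
            ("lysis", (lys.start, lys.end)),
        ):
            region = Region(s, e)
            orf = OrfCall(
                region=region,
                frame=(s - 1) % 3,
                start_codon=extract(genome, Region(s, s + 2)),
                protein=translate(extract(genome, region)),
            )
            genes.append(GeneAnnotation(role=role, orf=orf, confidence=1.0))
        truth = SyntheticTruth(
            genome=genome,
            genes=genes,
            lysis_mode=cfg.lysis_mode,
            elements=PlantedElements(
                five_prime_hairpin=b.elements["five_prime_hairpin"],
                operator_span=b.elements["operator_span"],
                operator_loop=b.elements["operator_loop"],
                utr_hairpins=b.elements["utr_hairpins"],
                utr_hairpin_loops=b.elements["utr_hairpin_loops"],
                ld_arm5=b.elements["ld_arm5"],
                ld_arm3=b.elements["ld_arm3"],
                v_linker=b.elements["v_linker"],
                u1_loop=b.elements["u1_loop"],
                pseudoknot_partner=b.elements["pseudoknot_partner"],
                lysis_sd=b.elements["lysis_sd"],
            ),
            seed=seed,
            config=cfg,
        )
        if not verify:
            return truth
        cand = evaluate_candidate(genome, truth.lysis.orf, ScreenConfig())
        if (
            cand.c1_length_ok
            and cand.c2_tm.has_tm
            and cand.c3_sd is not None
            and cand.c4_start_hairpin.passes
        ):
            return truth
    raise RuntimeError("could not generate a self-consistent genome")


# ---------------------------------------------------------------------------
# sequence evolution along a known tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionConfig:
    """Tree heights are expected substitutions/site per lineage."""

    tree: TreeNode
    alphabet: str = "ACGU"  # RNA by default; pass amino acids for proteins
    indel_rate: float = 0.0  # per-site probability per branch
    seed: int = 0


def evolve_family(
    root_seq: str, evo: EvolutionConfig
) -> tuple[list[tuple[str, str]], TreeNode]:
    """Simulate substitutions (Poisson per branch) down a fixed tree.

    Each site accumulates Poisson(branch length) substitution events, each
    replacing the current letter by one of the other letters uniformly
    (Jukes-Cantor-like for RNA).  Indels, when enabled, are single-site
    deletions/insertions.  Returns (label, sequence) leaves in tree order
    plus the (unchanged) true tree.
    """
    if not root_seq:
        raise ValueError("root sequence must be nonempty")
    letters = list(evo.alphabet)
    out: list[tuple[str, str]] = []

    def mutate(seq: str, t: float, rng) -> str:
        chars = list(seq)
        ks = rng.poisson(t, size=len(chars))
        for i, k in enumerate(ks):
            for _ in range(int(k)):
                others = [x for x in letters if x != chars[i]]
                chars[i] = others[rng.integers(0, len(others))]
        if evo.indel_rate > 0:
            keep = rng.random(len(chars)) >= evo.indel_rate / 2
            chars = [c for c, k in zip(chars, keep) if k]
            ins = rng.random(len(chars) + 1) < evo.indel_rate / 2
            built: list[str] = []
            for idx in range(len(chars) + 1):
                if ins[idx]:
                    built.append(letters[rng.integers(0, len(letters))])
                if idx < len(chars):
                    built.append(chars[idx])
            chars = built
        return "".join(chars)

    counter = [0]

    def walk(node: TreeNode, seq: str, parent_height: float) -> None:
        t = parent_height - node.height
        counter[0] += 1
        rng = np.random.default_rng([evo.seed & 0x7FFFFFFF, 8887, counter[0]])
        child_seq = mutate(seq, max(t, 0.0), rng)
        if node.is_leaf:
            out.append((node.name, child_seq))
        else:
            for c in node.children:
                walk(c, child_seq, node.height)

    walk(evo.tree, root_seq, evo.tree.height)
    return out, evo.tree


def example_tree_6() -> TreeNode:
    """A fixed ultrametric 6-taxon tree used in recovery tests:
    (((A,B),(C,D)),(E,F)) with cherry heights 0.03/0.03/0.05."""
    ab = TreeNode(children=[TreeNode(name="A"), TreeNode(name="B")], height=0.03)
    cd = TreeNode(children=[TreeNode(name="C"), TreeNode(name="D")], height=0.03)
    ef = TreeNode(children=[TreeNode(name="E"), TreeNode(name="F")], height=0.05)
    abcd = TreeNode(children=[ab, cd], height=0.08)
    return TreeNode(children=[abcd, ef], height=0.12)


def random_rna(length: int, seed: int) -> str:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 9973])
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))
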