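"""Detectors for the conserved RNA elements of levivirus genomes.

Four elements recur across the family and are searched for here: a stable
GC-rich hairpin at the extreme 5' end (implicated in replication), the
operator hairpin around the replicase start codon (the coat-protein binding
site that represses replicase translation), the 3'-UTR domain of stacked
hairpins closed by the long-distance interaction ld IX that bridges the 3'
terminus, and a putative long-distance pseudoknot partner for the loop of
the 3'-terminal hairpin U1.

Hairpin coordinates produced by :func:`extract_hairpins` are local to the
folded window; detectors shift them to 1-based genome coordinates before
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Optional

from ..seqio import GenomeRecord, Region, extract, gc_fraction, reverse_complement
from .energy import EnergyModel, can_pair, default_model
from .fold import SecondaryStructure, fold_mfe

#: Positional hairpin labels of the 3'-terminal domain (U1 = 3'-terminal).
U_LABELS = ("U1", "U2", "U3", "U4", "U5", "U6")


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop read off a nested structure.

    ``stem5``/``stem3`` are the two strands of the closing helix, ``loop``
    the unpaired loop between them; ``n_bp`` counts pairs in the helix
    (bulged positions inside the arm are allowed and recorded).
    """

    stem5: Region
    stem3: Region
    loop: Region
    loop_seq: str
    n_bp: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.stem5.end < self.loop.start <= self.loop.end < self.stem3.start):
            raise ValueError("hairpin stem/loop ordering violated")
        if self.n_bp < 1:
            raise ValueError("hairpin needs at least one pair")

    @property
    def span(self) -> Region:
        return Region(self.stem5.start, self.stem3.end)

    def shifted(self, delta: int) -> "Hairpin":
        def sh(r: Region) -> Region:
            return Region(r.start + delta, r.end + delta)

        return _dc_replace(
            self, stem5=sh(self.stem5), stem3=sh(self.stem3), loop=sh(self.loop)
        )


@dataclass(frozen=True)
class LongDistanceInteraction:
    """A duplex bridging the genome 3' terminus to an upstream stretch."""

    arm5: Region
    arm3: Region
    n_bp: int


@dataclass(frozen=True)
class PseudoknotCandidate:
    """An upstream pentamer (or longer) complementary to a hairpin loop."""

    loop_region: Region
    partner_region: Region
    distance_nt: int  # loop 5' start minus partner 3' end
    n_bp: int
    partner_seq: str


@dataclass(frozen=True)
class OperatorReport:
    hairpin: Optional[Hairpin]  # genome coordinates
    loop_adenine_minus4: Optional[bool]
    unpaired_purine_in_stem: Optional[bool]
    structure: SecondaryStructure
    window: Region


@dataclass(frozen=True)
class ThreePrimeUTR:
    ld: Optional[LongDistanceInteraction]
    hairpins: list[Hairpin]  # genome coordinates, labeled, 5'->3' order
    u1_loop_seq: str
    v_like_unpaired: Optional[Region]
    structure: SecondaryStructure
    window: Region


def _arm(pairmap: dict[int, int], close_i: int, close_j: int, max_bulge: int = 3):
    """Walk outward from a loop-closing pair, tolerating small bulges.

    Returns (pairs, bulged_positions) — 0-based, pairs ordered inner->outer.
    """
    pairs = [(close_i, close_j)]
    bulged: list[int] = []
    i, j = close_i, close_j
    maxpos = max(pairmap) if pairmap else -1
    while True:
        ni, gap5 = i - 1, 0
        while ni >= 0 and ni not in pairmap and gap5 <= max_bulge:
            ni -= 1
            gap5 += 1
        nj, gap3 = j + 1, 0
        while nj <= maxpos and nj not in pairmap and gap3 <= max_bulge:
            nj += 1
            gap3 += 1
        if ni < 0 or gap5 > max_bulge or gap3 > max_bulge or pairmap.get(ni) != nj:
            break
        bulged.extend(range(ni + 1, i))
        bulged.extend(range(j + 1, nj))
        pairs.append((ni, nj))
        i, j = ni, nj
    return pairs, sorted(bulged)


def extract_hairpins(structure: SecondaryStructure) -> list[Hairpin]:
    """One Hairpin per hairpin loop, 5'->3', in local 1-based coordinates.

    The helix is walked outward through bulges of up to 3 nt, so a stem
    interrupted by a bulged residue is reported as one hairpin.
    """
    pm = structure.pair_map
    n = len(structure.sequence)
    hairpins: list[Hairpin] = []
    i = 0
    while i < n:
        j = pm.get(i)
        if j is None or j < i:
            i += 1
            continue
        # is (i, j) a loop-closing pair? (no paired position strictly inside)
        if any(k in pm for k in range(i + 1, j)):
            i += 1
            continue
        arm_pairs, _ = _arm(pm, i, j)
        outer_i, outer_j = arm_pairs[-1]
        hairpins.append(
            Hairpin(
                stem5=Region(outer_i + 1, i + 1),
                stem3=Region(j + 1, outer_j + 1),
                loop=Region(i + 2, j),
                loop_seq=structure.sequence[i + 1 : j],
                n_bp=len(arm_pairs),
            )
        )
        i = j + 1
    hairpins.sort(key=lambda h: h.stem5.start)
    return hairpins


def hairpin_energy(structure: SecondaryStructure, hairpin: Hairpin,
                   model: EnergyModel | None = None) -> float:
    """Free energy (kcal/mol) of one stem-loop considered in isolation."""
    from .energy import evaluate

    sub = structure.sequence[hairpin.stem5.start - 1 : hairpin.stem3.end]
    db = structure.pairing[hairpin.stem5.start - 1 : hairpin.stem3.end]
    # positions pairing outside the hairpin cannot occur for a closed stem-loop
    return evaluate(sub, db, model)


def detect_five_prime_hairpin(
    genome: GenomeRecord,
    window_nt: int = 40,
    dg_max: float = -8.0,
    gc_min: float = 0.6,
    model: EnergyModel | None = None,
) -> Optional[Hairpin]:
    """The stable GC-rich hairpin at the genome 5' terminus, if present.

    Folds the first ``window_nt`` nucleotides and returns the 5'-most hairpin
    provided its isolated dG <= ``dg_max`` and its stem GC fraction >=
    ``gc_min``; genome coordinates (the window starts at nt 1, so local and
    genome coordinates coincide).
    """
    if window_nt > 60:
        raise ValueError("5' window capped at 60 nt")
    window = genome.sequence[: min(window_nt, genome.length)]
    structure = fold_mfe(window, model)
    hairpins = extract_hairpins(structure)
    if not hairpins:
        return None
    hp = hairpins[0]
    stem_seq = (
        structure.sequence[hp.stem5.start - 1 : hp.stem5.end]
        + structure.sequence[hp.stem3.start - 1 : hp.stem3.end]
    )
    if gc_fraction(stem_seq) < gc_min:
        return None
    if hairpin_energy(structure, hp, model) > dg_max:
        return None
    return hp


def detect_operator(
    genome: GenomeRecord,
    replicase_start: int,
    upstream_nt: int = 30,
    downstream_nt: int = 15,
    model: EnergyModel | None = None,
) -> OperatorReport:
    """The operator hairpin around the replicase initiation codon.

    Folds a window (default -30..+15 around the start codon's first nt) and
    returns the hairpin containing the start codon, with the two diagnostics
    of a coat-protein-binding operator: an adenine in the loop four
    nucleotides upstream of the start codon, and at least one unpaired
    purine bulged in the stem.
    """
    win_start = max(1, replicase_start - upstream_nt)
    win_end = min(genome.length, replicase_start + downstream_nt - 1 + 3)
    window_region = Region(win_start, win_end)
    structure = fold_mfe(extract(genome, window_region), model)
    delta = win_start - 1
    start_local = replicase_start - delta  # 1-based local
    chosen = None
    for hp in extract_hairpins(structure):
        if hp.span.start <= start_local <= hp.span.end:
            chosen = hp
            break
    if chosen is None:
        return OperatorReport(None, None, None, structure, window_region)
    pm = structure.pair_map
    # diagnostic 1: adenine in the loop, 4 nt upstream of the start codon
    pos_minus4 = start_local - 4  # local, 1-based
    in_loop = chosen.loop.contains(pos_minus4)
    loop_a = bool(in_loop and structure.sequence[pos_minus4 - 1] == "A")
    # diagnostic 2: unpaired purine within the stem arms
    _, bulged = _arm(pm, chosen.stem5.end - 1, chosen.stem3.start - 1)
    purine_bulge = any(structure.sequence[b] in "AG" for b in bulged)
    return OperatorReport(
        chosen.shifted(delta), loop_a, purine_bulge, structure, window_region
    )


def analyze_3utr(
    genome: GenomeRecord,
    replicase_end: int,
    tail_nt: int = 60,
    terminus_slack: int = 5,
    min_ld_bp: int = 4,
    model: EnergyModel | None = None,
) -> ThreePrimeUTR:
    """Fold and annotate the 3'-terminal domain.

    The 3' UTR plus up to ``tail_nt`` of the replicase tail is folded; the
    outermost duplex whose 3' arm reaches within ``terminus_slack`` nt of the
    terminus is reported as ld IX (when >= ``min_ld_bp`` pairs); hairpins
    inside the UTR are labeled U1, U2, ... from the 3' end (hairpins still in
    the replicase tail are labeled R1, R2, ... from the UTR inward); the
    unpaired stretch between the two 3'-terminal hairpins — the position
    where other phages carry the adenine-rich hairpin V — is reported when
    present.
    """
    utr_start = replicase_end + 1
    utr_len = genome.length - replicase_end
    if utr_len < 30:
        raise ValueError(f"3' UTR of {utr_len} nt is shorter than 30 nt")
    win_start = max(1, utr_start - tail_nt)
    window_region = Region(win_start, genome.length)
    structure = fold_mfe(extract(genome, window_region), model)
    delta = win_start - 1
    n = len(structure.sequence)
    pm = structure.pair_map

    # ld IX: outermost helix reaching the terminus
    ld = None
    terminal = [
        (i, j)
        for i, j in ((i, pm[i]) for i in sorted(pm) if pm[i] > i)
        if j >= n - terminus_slack
    ]
    if terminal:
        i, j = min(terminal)  # outermost
        nbp = 1
        while (i + nbp) in pm and pm[i + nbp] == j - nbp:
            nbp += 1
        if nbp >= min_ld_bp:
            ld = LongDistanceInteraction(
                arm5=Region(i + 1 + delta, i + nbp + delta),
                arm3=Region(j - nbp + 2 + delta, j + 1 + delta),
                n_bp=nbp,
            )

    hairpins = [hp.shifted(delta) for hp in extract_hairpins(structure)]
    utr_hairpins = [hp for hp in hairpins if hp.loop.start >= utr_start]
    tail_hairpins = [hp for hp in hairpins if hp.loop.start < utr_start]
    labeled: list[Hairpin] = []
    for idx, hp in enumerate(reversed(utr_hairpins)):  # 3' -> 5'
        label = U_LABELS[idx] if idx < len(U_LABELS) else f"U{idx + 1}"
        labeled.append(_dc_replace(hp, label=label))
    for idx, hp in enumerate(reversed(tail_hairpins)):
        labeled.append(_dc_replace(hp, label=f"R{idx + 1}"))
    labeled.sort(key=lambda h: h.stem5.start)

    u1_loop_seq = ""
    v_like = None
    if utr_hairpins:
        u1 = utr_hairpins[-1]
        u1_loop_seq = u1.loop_seq
        if len(utr_hairpins) >= 2:
            u2 = utr_hairpins[-2]
            lo, hi = u2.stem3.end + 1, u1.stem5.start - 1
            if hi >= lo:
                unpaired = [
                    p for p in range(lo, hi + 1) if (p - 1 - delta) not in pm
                ]
                if unpaired and len(unpaired) == hi - lo + 1:
                    v_like = Region(lo, hi)
    return ThreePrimeUTR(ld, labeled, u1_loop_seq, v_like, structure, window_region)


def pseudoknot_partner_search(
    genome: GenomeRecord,
    loop: Region,
    min_bp: int = 5,
    search_band: tuple[int, int] = (1000, 1400),
    allow_gu: bool = False,
) -> list[PseudoknotCandidate]:
    """Upstream stretches able to base-pair with a hairpin loop.

    Scans the band ``near_nt <= distance <= far_nt`` upstream of the loop
    (distance = loop 5' start minus partner 3' end) for windows whose
    sequence is the antiparallel complement of >= ``min_bp`` contiguous loop
    nucleotides.  Watson-Crick pairs only unless ``allow_gu``.  Candidates
    are maximal (not contained in a longer reported window) and ranked by
    pair count, then by proximity to the band center.
    """
    near_nt, far_nt = search_band
    if near_nt >= far_nt:
        raise ValueError("search band must satisfy near_nt < far_nt")
    loop_seq = extract(genome, loop)
    seq = genome.sequence

    def ok(a: str, b: str) -> bool:
        if can_pair(a, b):
            if allow_gu or {a, b} != {"G", "U"}:
                return True
        return False

    hits: list[PseudoknotCandidate] = []
    for length in range(len(loop_seq), min_bp - 1, -1):
        for off in range(0, len(loop_seq) - length + 1):
            sub = loop_seq[off : off + length]
            # partner runs antiparallel: partner[0] pairs sub[-1]
            for p_end in range(loop.start - near_nt, loop.start - far_nt - 1, -1):
                p_start = p_end - length + 1
                if p_start < 1 or p_end > len(seq):
                    continue
                window = seq[p_start - 1 : p_end]
                if all(ok(window[k], sub[length - 1 - k]) for k in range(length)):
                    region = Region(p_start, p_end)
                    if any(
                        h.partner_region.start <= p_start
                        and p_end <= h.partner_region.end
                        for h in hits
                    ):
                        continue
                    hits.append(
                        PseudoknotCandidate(
                            loop_region=loop,
                            partner_region=region,
                            distance_nt=loop.start - p_end,
                            n_bp=length,
                            partner_seq=window,
                        )
                    )
    center = (near_nt + far_nt) / 2
    hits.sort(key=lambda h: (-h.n_bp, abs(h.distance_nt - center), h.partner_region.start))
    return hits
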