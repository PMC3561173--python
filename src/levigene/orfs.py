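"""ORF enumeration and canonical levivirus gene-architecture assignment.

Leviviridae genomes carry maturation, coat and replicase cistrons in 5'->3'
order; small phages of this family initiate at AUG but also at GUG and UUG,
so the default start-codon set includes all three.  Architecture assignment
is a soft-scored search: among all ordered, non-nested ORF triples it
maximizes total coding length plus a band bonus reflecting the typical
Leviviridae protein sizes (coat is the short gene, replicase the long one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqio import (
    GenomeRecord,
    Region,
    START_CODONS,
    STOP_CODONS,
    extract,
    translate,
)

DEFAULT_START_CODONS = frozenset(START_CODONS)

#: Soft size bands (residues) used to recognize the three core genes.  These
#: are typical Leviviridae proportions, not hard filters; they are
#: configurable because the family shows real spread around them.
SIZE_BANDS_AA = {
    "maturation": (390, 450),
    "coat": (120, 140),
    "replicase": (530, 590),
}

CORE_ROLES = ("maturation", "coat", "replicase")


class ArchitectureNotFoundError(ValueError):
    """No maturation<coat<replicase triple could be assigned.

    Carries the best partial assignment in ``partial``.
    """

    def __init__(self, message: str, partial: list["GeneAnnotation"]):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class OrfCall:
    """A stop-terminated open reading frame.

    ``region.start`` is the first nt of the start codon; ``region.end`` the
    last nt of the stop codon.  ``frame`` is (start-1) mod 3.  ``primary``
    marks the longest call among nested starts sharing one stop codon.
    """

    region: Region
    frame: int
    start_codon: str
    protein: str
    primary: bool = True

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    @property
    def length_nt(self) -> int:
        return len(self.region)

    def __post_init__(self) -> None:
        if len(self.region) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if self.length_aa != len(self.region) // 3 - 1:
            raise ValueError("protein length inconsistent with ORF span")


@dataclass(frozen=True)
class GeneAnnotation:
    role: str  # maturation | coat | replicase | lysis | readthrough_A1 | unassigned
    orf: OrfCall
    confidence: float = 1.0


def _codon_at(seq: str, pos1: int) -> str:
    """Codon whose first nt is at 1-based position pos1."""
    return seq[pos1 - 1 : pos1 + 2]


def find_orfs(
    genome: GenomeRecord,
    start_codons: frozenset[str] | set[str] = DEFAULT_START_CODONS,
    min_length_aa: int = 30,
) -> list[OrfCall]:
    """All stop-terminated ORFs with >= ``min_length_aa`` residues.

    Nested starts sharing a stop codon in one frame are all reported; the
    longest (5'-most start) is flagged primary.  Sorted by start coordinate.
    """
    if min_length_aa < 1:
        raise ValueError("min_length_aa must be >= 1")
    seq = genome.sequence
    n = len(seq)
    # first in-frame stop at-or-after each position, per frame
    next_stop: dict[int, dict[int, int]] = {0: {}, 1: {}, 2: {}}
    for f in range(3):
        stop_pos = None  # start position of the next stop codon, scanning 3'->5'
        for p in range(n - 2 - ((n - 2 - (f + 1)) % 3), 0, -3):
            if _codon_at(seq, p) in STOP_CODONS:
                stop_pos = p
            next_stop[f][p] = stop_pos
    calls: list[OrfCall] = []
    by_stop: dict[tuple[int, int], list[int]] = {}
    for p in range(1, n - 1):
        codon = _codon_at(seq, p)
        if codon not in start_codons:
            continue
        f = (p - 1) % 3
        stop = next_stop[f].get(p)
        if stop is None or stop == p:
            continue
        length_aa = (stop + 3 - p) // 3 - 1
        if length_aa < min_length_aa:
            continue
        region = Region(p, stop + 2)
        protein = translate(extract(genome, region))
        calls.append(OrfCall(region=region, frame=f, start_codon=codon, protein=protein))
        by_stop.setdefault((f, stop), []).append(len(calls) - 1)
    # flag the longest call per (frame, stop) as primary
    out = list(calls)
    for (_, _), idxs in by_stop.items():
        best = min(idxs, key=lambda i: calls[i].region.start)
        for i in idxs:
            out[i] = replace(calls[i], primary=(i == best))
    out.sort(key=lambda o: (o.region.start, o.region.end))
    return out


def orfs_in_alternate_frames(
    genome: GenomeRecord,
    anchor: OrfCall,
    frame_offset: int,
    min_length_aa: int = 17,
    start_codons: frozenset[str] | set[str] = DEFAULT_START_CODONS,
) -> list[OrfCall]:
    """ORFs overlapping *anchor* whose frame is anchor.frame + offset (mod 3).

    Used to probe the canonical lysis-gene location: in most leviviruses the
    lysis gene overlaps the coat/replicase junction in a shifted frame.
    """
    if frame_offset not in (1, 2):
        raise ValueError("frame_offset must be +1 or +2")
    target = (anchor.frame + frame_offset) % 3
    hits = [
        o
        for o in find_orfs(genome, start_codons, min_length_aa)
        if o.frame == target and o.region.overlaps(anchor.region)
    ]
    return hits


def stop_positions_in_frame(genome: GenomeRecord, frame: int) -> list[int]:
    """1-based first-nt positions of all stop codons in the given frame."""
    seq = genome.sequence
    return [
        p
        for p in range(frame + 1, len(seq) - 1, 3)
        if _codon_at(seq, p) in STOP_CODONS
    ]


def _band_score(length_aa: int, band: tuple[int, int], scale: float = 100.0) -> float:
    lo, hi = band
    if lo <= length_aa <= hi:
        return 1.0
    dist = (lo - length_aa) if length_aa < lo else (length_aa - hi)
    return max(0.0, 1.0 - dist / scale)


def assign_core_genes(
    orfs: list[OrfCall],
    genome: GenomeRecord,
    size_bands: dict[str, tuple[int, int]] | None = None,
    max_overlap_nt: int = 45,
    band_weight_nt: float = 300.0,
) -> list[GeneAnnotation]:
    """Assign maturation/coat/replicase roles to an ORF list.

    Scans ordered, non-nested primary-ORF triples and maximizes total coding
    length plus ``band_weight_nt`` x the summed size-band score; consecutive
    genes may overlap by at most ``max_overlap_nt`` (small junction overlaps
    occur in real genomes).  Remaining ORFs are returned role "unassigned".
    Raises :class:`ArchitectureNotFoundError` (carrying the best partial
    assignment) when no valid triple exists.
    """
    bands = size_bands or SIZE_BANDS_AA
    cands = sorted(
        (o for o in orfs if o.primary),
        key=lambda o: (o.region.start, o.region.end),
    )

    def _partial(roles: list[tuple[str, OrfCall]]) -> list[GeneAnnotation]:
        used = {id(o) for _, o in roles}
        anns = [
            GeneAnnotation(
                role,
                o,
                _band_score(o.length_aa, bands[role]) if role in bands else 0.0,
            )
            for role, o in roles
        ]
        anns += [
            GeneAnnotation("unassigned", o, 0.0) for o in orfs if id(o) not in used
        ]
        return anns

    if len(cands) < 3:
        best_one = max(cands, key=lambda o: o.length_nt, default=None)
        partial = _partial([("unassigned", best_one)] if best_one else [])
        raise ArchitectureNotFoundError(
            f"architecture not found: only {len(cands)} candidate ORFs", partial
        )

    best_score = None
    best_triple = None
    m = len(cands)
    for i in range(m):
        a = cands[i]
        for j in range(i + 1, m):
            b = cands[j]
            if b.region.start <= a.region.start or b.region.end <= a.region.end:
                continue  # nested or unordered
            if a.region.end - b.region.start + 1 > max_overlap_nt:
                continue
            for k in range(j + 1, m):
                c = cands[k]
                if c.region.start <= b.region.start or c.region.end <= b.region.end:
                    continue
                if b.region.end - c.region.start + 1 > max_overlap_nt:
                    continue
                total_nt = a.length_nt + b.length_nt + c.length_nt
                band = (
                    _band_score(a.length_aa, bands["maturation"])
                    + _band_score(b.length_aa, bands["coat"])
                    + _band_score(c.length_aa, bands["replicase"])
                )
                score = total_nt + band_weight_nt * band
                key = (score, -a.region.start)
                if best_score is None or key > best_score:
                    best_score = key
                    best_triple = (a, b, c)
    if best_triple is None:
        longest = max(cands, key=lambda o: o.length_nt)
        raise ArchitectureNotFoundError(
            "architecture not found: no ordered non-nested ORF triple",
            _partial([("unassigned", longest)]),
        )
    a, b, c = best_triple
    roles = [("maturation", a), ("coat", b), ("replicase", c)]
    used = {id(o) for _, o in roles}
    anns = [
        GeneAnnotation(role, o, round(_band_score(o.length_aa, bands[role]), 3))
        for role, o in roles
    ]
    anns += [GeneAnnotation("unassigned", o, 0.0) for o in orfs if id(o) not in used]
    anns.sort(key=lambda g: (g.orf.region.start, g.orf.region.end))
    return anns


def core_gene_map(annotations: list[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    return {a.role: a for a in annotations if a.role in CORE_ROLES}
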