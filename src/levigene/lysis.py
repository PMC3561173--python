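"""Four-criterion lysis-gene screen for levivirus genomes.

Levivirus lysis proteins are short (>= 34 residues in known phages), carry a
single transmembrane helix, initiate at sometimes unusual start codons (UUG)
backed by a Shine-Dalgarno motif, and sit on weak, AU-rich start-codon
hairpins that leave the initiation region accessible.  The screen evaluates
every non-core ORF against these four criteria:

1. significant length (>= 34 aa, the shortest known levivirus lysis protein);
2. a predicted transmembrane helix (Kyte-Doolittle sliding window, in place
   of an HMM-based server prediction);
3. a Shine-Dalgarno motif (contiguous >= 4 nt match to AGGAGG) at 4-14 nt
   spacing upstream of the start codon;
4. a thermodynamically weak start-codon hairpin (dG >= -6 kcal/mol over a
   30-nt window centered on the start).

Candidates are ranked by a weighted composite score.  The screen also probes
the canonical lysis-gene locations (coat/replicase junction frames,
replicase-internal frames, 5' of maturation) so that a negative result at
the usual position is itself reportable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .orfs import (
    DEFAULT_START_CODONS,
    GeneAnnotation,
    OrfCall,
    core_gene_map,
    find_orfs,
    orfs_in_alternate_frames,
    stop_positions_in_frame,
)
from .seqio import GenomeRecord, Region, SequenceError, au_fraction, extract
from .structure import SecondaryStructure, extract_hairpins, fold_mfe

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Substrings of the full Shine-Dalgarno consensus AGGAGG, longest first.
_SD_CONSENSUS = "AGGAGG"
_SD_MOTIFS = sorted(
    {
        _SD_CONSENSUS[i : i + L]
        for L in range(4, len(_SD_CONSENSUS) + 1)
        for i in range(len(_SD_CONSENSUS) - L + 1)
    },
    key=len,
    reverse=True,
)


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the screen; echoed verbatim into reports."""

    start_codons: frozenset[str] = DEFAULT_START_CODONS
    min_length_aa: int = 34  # shortest known levivirus lysis protein (AP205)
    max_typical_length_aa: int = 120
    tm_window: int = 19
    tm_threshold: float = 1.6  # Kyte-Doolittle surface/buried criterion
    sd_window_nt: int = 25
    sd_spacing: tuple[int, int] = (4, 14)
    sd_min_match: int = 4
    hairpin_dg_threshold: float = -6.0  # kcal/mol; weaker (higher) passes
    hairpin_window_nt: int = 30
    weight_tm: float = 0.4
    weight_sd: float = 0.3
    weight_hairpin: float = 0.2
    weight_length: float = 0.1

    def as_dict(self) -> dict:
        return {
            "start_codons": sorted(self.start_codons),
            "min_length_aa": self.min_length_aa,
            "max_typical_length_aa": self.max_typical_length_aa,
            "tm_window": self.tm_window,
            "tm_threshold": self.tm_threshold,
            "sd_window_nt": self.sd_window_nt,
            "sd_spacing": list(self.sd_spacing),
            "sd_min_match": self.sd_min_match,
            "hairpin_dg_threshold": self.hairpin_dg_threshold,
            "hairpin_window_nt": self.hairpin_window_nt,
            "weights": {
                "tm": self.weight_tm,
                "sd": self.weight_sd,
                "hairpin": self.weight_hairpin,
                "length": self.weight_length,
            },
            "sd_spacing_convention": (
                "spacing_nt counts nucleotides strictly between the motif 3' "
                "end and the start codon's first nt"
            ),
        }


@dataclass(frozen=True)
class SDSite:
    motif_seq: str
    motif_region: Region
    spacing_nt: int  # nt strictly between motif 3' end and start codon
    score: int  # contiguous match length to AGGAGG (4..6)


@dataclass(frozen=True)
class TMPrediction:
    window: Region  # protein coordinates, 1-based inclusive
    mean_hydropathy: float
    has_tm: bool


@dataclass(frozen=True)
class StartHairpinResult:
    dg: float
    au_fraction: float
    passes: bool
    structure: SecondaryStructure
    window: Region


@dataclass(frozen=True)
class LysisCandidate:
    orf: OrfCall
    c1_length_ok: bool
    c2_tm: TMPrediction
    c3_sd: Optional[SDSite]
    c4_start_hairpin: StartHairpinResult
    composite_score: float
    rank: int = 0


@dataclass(frozen=True)
class ScreenResult:
    candidates: list[LysisCandidate]
    location_report: dict
    config: ScreenConfig


def find_sd(
    genome: GenomeRecord,
    start: int,
    window_nt: int = 25,
    spacing: tuple[int, int] = (4, 14),
    min_match: int = 4,
) -> Optional[SDSite]:
    """Best Shine-Dalgarno motif upstream of a start codon, or None.

    Looks for the longest contiguous substring of AGGAGG (>= ``min_match``
    nt) ending ``spacing[0]``..``spacing[1]`` nt upstream of the start;
    among equal-length matches the one with spacing closest to 9 nt (the
    canonical levivirus arrangement) wins.  spacing_nt counts nucleotides
    strictly between the motif's 3' end and the start codon's first nt.
    """
    if start <= window_nt:
        window_nt = start - 1
    best: Optional[SDSite] = None
    for motif in _SD_MOTIFS:
        if len(motif) < min_match:
            continue
        L = len(motif)
        for sp in range(spacing[0], spacing[1] + 1):
            m_end = start - 1 - sp
            m_start = m_end - L + 1
            if m_start < 1 or m_end > genome.length or start - m_start > window_nt + L:
                continue
            if genome.sequence[m_start - 1 : m_end] == motif:
                site = SDSite(motif, Region(m_start, m_end), sp, L)
                if (
                    best is None
                    or site.score > best.score
                    or (site.score == best.score
                        and abs(site.spacing_nt - 9) < abs(best.spacing_nt - 9))
                ):
                    best = site
    return best


def predict_tm(
    protein: str, window: int = 19, threshold: float = 1.6
) -> TMPrediction:
    """Sliding-window Kyte-Doolittle transmembrane-helix call.

    A protein shorter than 15 aa cannot be evaluated; between 15 aa and the
    window size the whole protein is one window.  ``has_tm`` is true iff the
    maximal window mean hydropathy reaches ``threshold``.
    """
    n = len(protein)
    if n < 15:
        raise SequenceError(f"protein of {n} aa is too short to evaluate")
    w = min(window, n)
    values = [KYTE_DOOLITTLE[a] for a in protein]
    best_mean, best_start = None, 0
    running = sum(values[:w])
    for s in range(0, n - w + 1):
        if s > 0:
            running += values[s + w - 1] - values[s - 1]
        mean = running / w
        if best_mean is None or mean > best_mean + 1e-12:
            best_mean, best_start = mean, s
    return TMPrediction(
        window=Region(best_start + 1, best_start + w),
        mean_hydropathy=best_mean,
        has_tm=best_mean >= threshold,
    )


def start_hairpin_stability(
    genome: GenomeRecord,
    start: int,
    window_nt: int = 30,
    dg_threshold: float = -6.0,
    model=None,
) -> StartHairpinResult:
    """Fold the start-codon context and judge its thermodynamic weakness.

    A 30-nt window centered on the start codon is folded; the criterion
    passes when the window's dG is above (weaker than) ``dg_threshold`` and
    the start codon sits in or adjacent (within 3 nt) to a hairpin — or when
    the window forms no hairpin at all, which is maximally accessible.
    """
    up = (window_nt - 3) // 2
    lo = max(1, start - up)
    hi = min(genome.length, lo + window_nt - 1)
    lo = max(1, hi - window_nt + 1)
    window = Region(lo, hi)
    structure = fold_mfe(extract(genome, window), model)
    hairpins = extract_hairpins(structure)
    start_local = start - lo + 1
    near = (
        not hairpins
        or any(
            h.span.start - 3 <= start_local <= h.span.end + 3 for h in hairpins
        )
    )
    passes = structure.energy >= dg_threshold and near
    return StartHairpinResult(
        dg=structure.energy,
        au_fraction=round(au_fraction(structure.sequence), 4),
        passes=passes,
        structure=structure,
        window=window,
    )


def _length_score(aa: int, cfg: ScreenConfig) -> float:
    if aa < cfg.min_length_aa:
        return 0.0
    if aa <= cfg.max_typical_length_aa:
        return 1.0
    return max(0.0, 1.0 - (aa - cfg.max_typical_length_aa) / 200.0)


def evaluate_candidate(
    genome: GenomeRecord, orf: OrfCall, cfg: ScreenConfig
) -> LysisCandidate:
    tm = predict_tm(orf.protein, cfg.tm_window, cfg.tm_threshold)
    sd = find_sd(
        genome, orf.region.start, cfg.sd_window_nt, cfg.sd_spacing, cfg.sd_min_match
    )
    hp = start_hairpin_stability(
        genome, orf.region.start, cfg.hairpin_window_nt, cfg.hairpin_dg_threshold
    )
    length_ok = orf.length_aa >= cfg.min_length_aa
    score = (
        cfg.weight_tm * (1.0 if tm.has_tm else 0.0)
        + cfg.weight_sd * ((sd.score / 6.0) if sd else 0.0)
        + cfg.weight_hairpin * (1.0 if hp.passes else 0.0)
        + cfg.weight_length * _length_score(orf.length_aa, cfg)
    )
    return LysisCandidate(
        orf=orf,
        c1_length_ok=length_ok,
        c2_tm=tm,
        c3_sd=sd,
        c4_start_hairpin=hp,
        composite_score=round(score, 6),
    )


def _probe_locations(
    genome: GenomeRecord,
    core: dict[str, GeneAnnotation],
    candidates: list[LysisCandidate],
) -> dict:
    """Reproduce the canonical-location elimination logic.

    Reports, per location known to host a levivirus lysis gene, whether any
    screened candidate lies there, plus the alternate-frame ORF scan over
    the coat gene and whether the +2 frame runs stop-free into replicase.
    """
    report: dict = {}
    coat = core.get("coat")
    repl = core.get("replicase")
    mat = core.get("maturation")
    if coat is not None:
        for off in (1, 2):
            alt = orfs_in_alternate_frames(genome, coat.orf, off, min_length_aa=17)
            report[f"coat_frame_plus{off}_orfs"] = [
                {"start": o.region.start, "end": o.region.end, "length_aa": o.length_aa}
                for o in alt
            ]
        if repl is not None:
            plus2_frame = (coat.orf.frame + 2) % 3
            stops = [
                p
                for p in stop_positions_in_frame(genome, plus2_frame)
                if coat.orf.region.start <= p < repl.orf.region.start
            ]
            report["coat_plus2_stop_free_to_replicase"] = not stops
    def _at(pred) -> bool:
        return any(pred(c.orf) for c in candidates)

    if coat is not None and repl is not None:
        junction = Region(coat.orf.region.start, repl.orf.region.start)
        report["candidate_at_coat_replicase_junction"] = _at(
            lambda o: o.region.overlaps(junction) and o.frame != coat.orf.frame
        )
    if repl is not None:
        report["candidate_within_replicase"] = _at(
            lambda o: repl.orf.region.start <= o.region.start
            and o.region.end <= repl.orf.region.end
            and o.frame != repl.orf.frame
        )
    if mat is not None:
        report["candidate_five_prime_of_maturation"] = _at(
            lambda o: o.region.start < mat.orf.region.start
        )
    return report


def screen(
    genome: GenomeRecord,
    annotation: list[GeneAnnotation],
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Rank every non-core ORF by the four lysis-gene criteria.

    An empty candidate list is a valid scientific result (no lysis gene
    found under the screen's thresholds), not an error.
    """
    cfg = config or ScreenConfig()
    core = core_gene_map(annotation)
    # Exclude core genes and their in-frame truncations (same stop, same
    # frame): those are alternative starts of a core cistron, not new genes.
    core_stops = {(a.orf.region.end, a.orf.frame) for a in core.values()}
    orfs = find_orfs(genome, cfg.start_codons, cfg.min_length_aa)
    pool = [o for o in orfs if (o.region.end, o.frame) not in core_stops]
    evaluated = [evaluate_candidate(genome, o, cfg) for o in pool]
    evaluated.sort(key=lambda c: (-c.composite_score, c.orf.region.start))
    ranked = [
        LysisCandidate(
            orf=c.orf,
            c1_length_ok=c.c1_length_ok,
            c2_tm=c.c2_tm,
            c3_sd=c.c3_sd,
            c4_start_hairpin=c.c4_start_hairpin,
            composite_score=c.composite_score,
            rank=i + 1,
        )
        for i, c in enumerate(evaluated)
    ]
    return ScreenResult(
        candidates=ranked,
        location_report=_probe_locations(genome, core, ranked),
        config=cfg,
    )
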