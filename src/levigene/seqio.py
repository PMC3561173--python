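"""Sequence I/O, the coordinate convention, and extraction/translation primitives.

All coordinates throughout the package are 1-based and fully inclusive on the
plus strand, matching the convention genome annotations of single-segment
positive-sense RNA phages are reported in (e.g. a lysis gene "between
nucleotides 2991-3104" spans 3104 - 2991 + 1 = 114 nt).  Input sequences may
be DNA or RNA in either case; they are normalized to uppercase RNA on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
_VALID_INPUT = frozenset("ACGTUacgtu")

#: Start codons recognized in bacterial initiation; all are decoded as
#: formyl-Met, so the first residue of any ORF is reported as M.
START_CODONS = frozenset({"AUG", "GUG", "UUG"})
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

# NCBI translation table 11 (bacterial), RNA codons.
_TABLE11 = CodonTable.unambiguous_rna_by_id[11]


class SequenceError(ValueError):
    """Raised on malformed sequence input (bad alphabet, bad FASTA)."""


class CoordinateError(ValueError):
    """Raised when a region falls outside its genome."""


@dataclass(frozen=True)
class Region:
    """A 1-based, fully inclusive span on the plus strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"invalid region {self.start}-{self.end}: need 1 <= start <= end"
            )
        if self.strand != "+":
            raise CoordinateError("only plus-strand regions are supported")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Region") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class GenomeRecord:
    """A single genome (or any sequence) as normalized uppercase RNA."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_rna(seq: str) -> str:
    """Uppercase and transcribe T->U; reject anything outside {A,C,G,T,U}."""
    for i, ch in enumerate(seq):
        if ch not in _VALID_INPUT:
            raise SequenceError(
                f"invalid character {ch!r} at position {i + 1} "
                "(expected A/C/G/T/U in either case)"
            )
    out = seq.upper().replace("T", "U")
    if not out:
        raise SequenceError("empty sequence")
    return out


def load_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords, preserving input order.

    DNA is silently transcribed to RNA and lowercase is uppercased.  An empty
    file raises ``SequenceError("no records")``; an invalid character raises
    with the offending record and position named.
    """
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(
                GenomeRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
            )
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    if not records:
        raise SequenceError("no records")
    return records


def write_fasta(records: Sequence[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def extract(genome: GenomeRecord, region: Region) -> str:
    """Return the subsequence covered by *region*; extract(g, (i, i)) is the
    i-th character."""
    if region.end > genome.length:
        raise CoordinateError(
            f"region end {region.end} exceeds genome length {genome.length}"
        )
    return genome.sequence[region.start - 1 : region.end]


def translate(orf_rna: str, include_stop_check: bool = True) -> str:
    """Translate an ORF with bacterial initiation (table 11).

    The first codon, if it is a recognized start codon (AUG/GUG/UUG), is
    decoded as M regardless of its elongation meaning; this is how a
    UUG-initiated 114-nt ORF yields a 37-residue product.  With
    ``include_stop_check`` the last codon must be a stop and no internal stop
    may occur; the stop is not included in the returned protein.
    """
    seq = normalize_rna(orf_rna)
    if len(seq) % 3 != 0:
        raise SequenceError(f"ORF length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if include_stop_check:
        if codons[-1] not in STOP_CODONS:
            raise SequenceError(f"last codon {codons[-1]} is not a stop codon")
        codons = codons[:-1]
    protein = []
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise SequenceError(
                f"internal stop codon {codon} at codon {idx + 1} "
                f"(nt {3 * idx + 1}-{3 * idx + 3})"
            )
        if idx == 0 and codon in START_CODONS:
            protein.append("M")
        else:
            protein.append(_TABLE11.forward_table[codon])
    return "".join(protein)


def write_gff3(
    genome: GenomeRecord,
    features: Iterable,
    path: str | Path,
    source: str = "levigene",
) -> None:
    """Write gene + CDS features as GFF3 (1-based inclusive, plus strand).

    *features* are GeneAnnotation-like objects exposing ``role`` and
    ``orf.region``; unassigned ORFs are written with role "unassigned".
    """
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {genome.length}"]
    for i, ann in enumerate(features, start=1):
        region = ann.orf.region
        gid = f"gene{i:02d}_{ann.role}"
        attrs = f"ID={gid};Name={ann.role};role={ann.role}"
        for ftype in ("gene", "CDS"):
            lines.append(
                "\t".join(
                    [
                        genome.id,
                        source,
                        ftype,
                        str(region.start),
                        str(region.end),
                        ".",
                        "+",
                        "0" if ftype == "CDS" else ".",
                        attrs if ftype == "gene" else f"ID={gid}.cds;Parent={gid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def au_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("U")) / len(seq)


_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
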