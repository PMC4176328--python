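"""Coordinate conventions, genome access and splice-site dinucleotide taxonomy.

All genomic intervals in this package are 0-based, half-open ``[start, end)``,
on the forward strand of the reference. A :class:`Junction` is the *intron*:
``start`` is the first intronic base, ``end`` is one past the last intronic
base. Donor and acceptor dinucleotides are always reported in transcript
orientation, i.e. reverse-complemented for minus-strand junctions.

An intron is *canonical* when its terminal dinucleotides are GT-AG, GC-AG or
AT-AC; every other pair is a non-canonical candidate that the downstream
filters and the PWM classifier must vet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from Bio import SeqIO

__all__ = [
    "Genome",
    "Junction",
    "DinucleotidePair",
    "JunctionCategory",
    "CategoryValue",
    "CANONICAL_PAIRS",
    "revcomp",
    "extract_dinucleotides",
    "categorize_dinucleotides",
    "CoordinateError",
    "ChromosomeNotFound",
    "DegenerateIntronError",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Dinucleotide pairs recognised by the major (U2) and minor (U12) spliceosome.
CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}


class CoordinateError(ValueError):
    """Interval outside chromosome bounds (never silently clipped)."""


class ChromosomeNotFound(KeyError):
    """Chromosome name absent from the genome."""


class DegenerateIntronError(ValueError):
    """Intron too short to carry two terminal dinucleotides."""


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """In-memory genome: chromosome name -> uppercase sequence.

    Retrieval is strictly 0-based half-open and bounds-checked; asking for
    bases beyond a chromosome end raises :class:`CoordinateError` rather
    than returning a truncated string. Lowercase (soft-masked) input bases
    are uppercased on load.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        """Load a multi-record, line-wrapped FASTA. Names are kept verbatim."""
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq)
        return cls(seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        try:
            return len(self.sequences[chrom])
        except KeyError:
            raise ChromosomeNotFound(chrom) from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return ``sequence[start:end)``; out-of-bounds is an error."""
        try:
            seq = self.sequences[chrom]
        except KeyError:
            raise ChromosomeNotFound(chrom) from None
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(
                f"interval [{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]


@dataclass
class Junction:
    """A strand-aware intron interval with per-source support and coverage.

    ``support`` counts *distinct supporting sequences* per data source;
    ``coverage`` counts reads per sample. Intron length may be as small as
    1 nt (the alignment setting this package consumes allows it), although
    dinucleotide extraction requires >= 2 nt.
    """

    chrom: str
    start: int
    end: int
    strand: str
    support: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)
    soft_masked: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"junction end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for mapping in (self.support, self.coverage):
            for key, v in mapping.items():
                if not isinstance(v, int) or v < 0:
                    raise ValueError(f"count for {key!r} must be a non-negative int")

    @property
    def intron_length(self) -> int:
        return self.end - self.start

    @property
    def key(self):
        """Identity of the intron interval (chrom, start, end, strand)."""
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def donor_pos(self) -> int:
        """Genomic position of the first intronic base on the transcript 5' side."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor_pos(self) -> int:
        """Genomic position of the last intronic base on the transcript 3' side."""
        return self.end - 1 if self.strand == "+" else self.start

    def total_coverage(self) -> int:
        return sum(self.coverage.values())

    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass(frozen=True)
class DinucleotidePair:
    """Donor and acceptor 2-mers of an intron, in transcript orientation."""

    donor: str
    acceptor: str

    def __post_init__(self):
        for mer in (self.donor, self.acceptor):
            if len(mer) != 2 or any(b not in "ACGTN" for b in mer):
                raise ValueError(f"invalid dinucleotide {mer!r}")

    def __str__(self) -> str:
        return f"{self.donor}-{self.acceptor}"


class CategoryValue(Enum):
    CANONICAL = "CANONICAL"
    NONCANONICAL_CANDIDATE = "NONCANONICAL_CANDIDATE"


@dataclass(frozen=True)
class JunctionCategory:
    value: CategoryValue
    subtype: str | None = None  # "GT-AG", "GC-AG" or "AT-AC" when canonical
    ambiguous_base: bool = False  # an N occurred in either dinucleotide

    @property
    def is_canonical(self) -> bool:
        return self.value is CategoryValue.CANONICAL


def extract_dinucleotides(genome: Genome, junction: Junction) -> DinucleotidePair:
    """Read the terminal dinucleotides of an intron in transcript orientation.

    On the plus strand the donor is ``genome[start, start+2)`` and the
    acceptor ``genome[end-2, end)``; on the minus strand both are taken from
    the opposite intron end and reverse-complemented.
    """
    if junction.intron_length < 2:
        raise DegenerateIntronError(
            f"intron of length {junction.intron_length} has no terminal dinucleotides"
        )
    left = genome.fetch(junction.chrom, junction.start, junction.start + 2)
    right = genome.fetch(junction.chrom, junction.end - 2, junction.end)
    if junction.strand == "+":
        return DinucleotidePair(donor=left, acceptor=right)
    return DinucleotidePair(donor=revcomp(right), acceptor=revcomp(left))


def categorize_dinucleotides(pair: DinucleotidePair) -> JunctionCategory:
    """Canonical iff the pair is GT-AG, GC-AG or AT-AC.

    Any N in either 2-mer is never called canonical; such pairs come back as
    non-canonical candidates flagged ``ambiguous_base`` so callers can keep
    assembly gaps out of both the canonical set and downstream claims.
    """
    if "N" in pair.donor or "N" in pair.acceptor:
        return JunctionCategory(CategoryValue.NONCANONICAL_CANDIDATE, ambiguous_base=True)
    key = (pair.donor, pair.acceptor)
    if key in CANONICAL_PAIRS:
        return JunctionCategory(CategoryValue.CANONICAL, subtype=f"{key[0]}-{key[1]}")
    return JunctionCategory(CategoryValue.NONCANONICAL_CANDIDATE)
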