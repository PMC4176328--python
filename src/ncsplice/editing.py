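"""A-to-I editing at splice-site dinucleotides.

Inosine pairs like guanosine both in the spliceosome and on the sequencer,
so an adenosine within a terminal dinucleotide that shows consistent A>G
mismatches in RNA-seq pileups behaves as a G: an AT-AG donor or GT-AA
acceptor is effectively canonical GT-AG once edited. This module scores
pileup evidence at the four terminal-dinucleotide positions and recodes
passing adenosines, reporting whether the edited pair became canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import CANONICAL_PAIRS, DinucleotidePair

__all__ = [
    "EditingEvidence",
    "detect_editing",
    "recode_edited",
    "load_pileup_tsv",
    "load_edited_sites_table",
]


@dataclass
class EditingEvidence:
    """A>G evidence at one transcript-strand adenosine."""

    chrom: str
    position: int
    ref_base: str
    count_a: int
    count_g: int
    fraction: float
    passes: bool


def detect_editing(
    chrom: str,
    position: int,
    ref_base: str,
    counts: dict,
    min_reads: int = 3,
    min_fraction: float = 0.2,
) -> EditingEvidence:
    """Score one pileup row (transcript-strand counts) for A-to-I editing.

    Passes iff the reference base is A, the G count reaches ``min_reads`` and
    the editing fraction G/(A+G) reaches ``min_fraction``. Genomic T>C on the
    minus strand must be translated to transcript-strand A>G by the caller.
    A missing pileup row is a distinct no-data condition and must not be
    passed here as zeros.
    """
    a = int(counts.get("A", 0))
    g = int(counts.get("G", 0))
    total = a + g
    fraction = g / total if total else 0.0
    passes = ref_base == "A" and g >= min_reads and fraction >= min_fraction
    return EditingEvidence(
        chrom=chrom, position=position, ref_base=ref_base,
        count_a=a, count_g=g, fraction=fraction, passes=passes,
    )


def recode_edited(pair: DinucleotidePair, evidence: dict) -> tuple:
    """Replace edited adenosines by G and test whether the pair went canonical.

    ``evidence`` maps positions within the pair — ``("donor", 0|1)`` or
    ``("acceptor", 0|1)`` — to :class:`EditingEvidence`. Only A->G
    substitutions are possible by construction; evidence at a non-A position
    is a contract error. Returns ``(edited_pair, became_canonical)``.
    Recoding is idempotent: an already-G base has no A left to edit.
    """
    donor = list(pair.donor)
    acceptor = list(pair.acceptor)
    for (side, idx), ev in evidence.items():
        mer = donor if side == "donor" else acceptor
        if mer[idx] != "A":
            raise ValueError(
                f"editing evidence at non-A position {side}[{idx}]={mer[idx]}"
            )
        if ev.passes:
            mer[idx] = "G"
    edited = DinucleotidePair(donor="".join(donor), acceptor="".join(acceptor))
    return edited, (edited.donor, edited.acceptor) in CANONICAL_PAIRS


def load_edited_sites_table(path=None) -> list:
    """Known human splice sites converted to canonical form by A-to-I editing.

    Each row gives the gene, intron type (U2- or U12-like), the pre-editing
    donor/acceptor dinucleotides and which adenosine is edited. The packaged
    default table lists the seven published human cases (four GT-AA
    acceptor-edited, three AT-AG donor-edited sites).
    """
    if path is None:
        from importlib import resources

        path = resources.files("ncsplice").joinpath("data/edited_sites_table.tsv")
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            f["edited_index"] = int(f["edited_index"])
            rows.append(f)
    return rows


def load_pileup_tsv(path) -> dict:
    """Read per-base pileup counts: chrom, position, strand, countA..countT.

    Returns ``{(chrom, position, strand): {"A": n, "C": n, "G": n, "T": n}}``.
    Positions are 0-based; counts are transcript-strand.
    """
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "position", "strand"]:
            raise ValueError("pileup TSV must start with chrom/position/strand")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out[(f[0], int(f[1]), f[2])] = {
                "A": int(f[3]), "C": int(f[4]), "G": int(f[5]), "T": int(f[6])
            }
    return out
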