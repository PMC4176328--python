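"""Cross-species junction conservation via precomputed coordinate mappings.

A junction is tested against another species' junction set after translating
its coordinates through a user-supplied (LiftOver-style, precomputed) interval
mapping. The test is strict: *conserved* requires the identical mapped
interval to exist in the other set AND the other genome to read the same
terminal dinucleotides; a coordinate match with different dinucleotides is
reported separately (splice-site gain/loss across lineages), as are lookup
misses and unmappable junctions. The four outcomes partition every input.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Genome, Junction, extract_dinucleotides

__all__ = ["Outcome", "CoordinateMapping", "load_mapping_tsv", "is_conserved"]


class Outcome:
    CONSERVED = "CONSERVED"
    COORD_MATCH_DINUC_DIFF = "COORD_MATCH_DINUC_DIFF"
    NOT_FOUND = "NOT_FOUND"
    UNMAPPED = "UNMAPPED"


@dataclass
class CoordinateMapping:
    """Single-valued source-interval -> target-interval map.

    Keys and values are ``(chrom, start, end, strand)``. Unmapped intervals
    are absent, never zero-filled. A record whose target interval is
    inverted (end <= start) is rejected on load as an inconsistent mapping.
    """

    records: dict

    def lookup(self, junction: Junction):
        return self.records.get(junction.key)

    @classmethod
    def identity(cls, junctions) -> "CoordinateMapping":
        """Map every junction onto itself (same-genome comparisons)."""
        return cls(records={j.key: j.key for j in junctions})


def load_mapping_tsv(path) -> CoordinateMapping:
    """Columns: chrom, start, end, strand, t_chrom, t_start, t_end, t_strand."""
    records = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            src = (f[0], int(f[1]), int(f[2]), f[3])
            tgt = (f[4], int(f[5]), int(f[6]), f[7])
            if tgt[2] <= tgt[1]:
                raise ValueError(
                    f"{path}:{lineno}: inverted target interval without strand flip"
                )
            records[src] = tgt
    return CoordinateMapping(records=records)


def is_conserved(
    junction: Junction,
    genome: Genome,
    mapping: CoordinateMapping,
    other_species_junctions,
    other_genome: Genome,
) -> tuple:
    """Conservation outcome of one junction in another species.

    Returns ``(outcome, other_dinucleotides | None)``. The other-species set
    must have been extracted with the same pipeline rules for the comparison
    to be meaningful; "same coordinates" is exact interval equality after
    mapping, with no slack window.
    """
    target = mapping.lookup(junction)
    if target is None:
        return Outcome.UNMAPPED, None
    other_keys = {
        j.key if isinstance(j, Junction) else tuple(j) for j in other_species_junctions
    }
    if target not in other_keys:
        return Outcome.NOT_FOUND, None
    chrom, start, end, strand = target
    other_pair = extract_dinucleotides(other_genome, Junction(chrom, start, end, strand))
    this_pair = extract_dinucleotides(genome, junction)
    if other_pair == this_pair:
        return Outcome.CONSERVED, other_pair
    return Outcome.COORD_MATCH_DINUC_DIFF, other_pair
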