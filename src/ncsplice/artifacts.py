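"""Artifact signatures among non-U2/U12 candidates.

Two classes of technical artifacts masquerade as non-canonical introns.
Homopolymer-associated indel errors make reads misalign a few bases off a
real canonical junction: the signature is a candidate whose donor AND
acceptor both lie within 10 nt of a canonical junction, typically flanked by
an exonic homopolymer run of >= 5 nt. Reverse-transcriptase template
switching creates deletion products that look like introns: the signature is
a long direct repeat at the junction and high %GC. Candidates are
partitioned exhaustively and the raw measurements are kept alongside the
partition so users can re-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ambiguity import enumerate_placements
from .core import Genome, Junction

__all__ = [
    "Partition",
    "ArtifactConfig",
    "ArtifactReport",
    "near_canonical_partition",
    "homopolymer_run",
    "gc_fraction",
    "partition_candidates",
]


class Partition:
    NEAR_CANONICAL_HOMOPOLYMER = "NEAR_CANONICAL_HOMOPOLYMER"
    NEAR_CANONICAL_OTHER = "NEAR_CANONICAL_OTHER"
    TEMPLATE_SWITCH_LIKE = "TEMPLATE_SWITCH_LIKE"
    UNEXPLAINED = "UNEXPLAINED"


@dataclass
class ArtifactConfig:
    max_dist: int = 10        # nt, near-canonical bound (both ends)
    min_run: int = 5          # nt, flanking homopolymer run
    repeat_min: int = 6       # nt, template-switch direct-repeat length
    gc_min: float = 0.6       # template-switch %GC bound
    gc_region: str = "intron"  # or "intron_flanks" (intron +/- 100 nt)


@dataclass
class ArtifactReport:
    junction_key: tuple
    partition: str
    donor_distance: int | None
    acceptor_distance: int | None
    homopolymer_run: int
    direct_repeat_length: int
    gc_fraction: float


def near_canonical_partition(
    candidate: Junction, canonical_set, max_dist: int = 10
):
    """Is the candidate within ``max_dist`` of a canonical junction at BOTH ends?

    Distances are measured between like ends (donor to donor, acceptor to
    acceptor) on the same chromosome and strand; the best (smallest-maximum)
    canonical neighbour defines the reported per-end distances. Returns
    ``(flag, donor_distance, acceptor_distance)``; distances are None when no
    canonical junction shares the chromosome/strand.
    """
    best = None
    for c in canonical_set:
        if c.chrom != candidate.chrom or c.strand != candidate.strand:
            continue
        dd = abs(c.donor_pos - candidate.donor_pos)
        da = abs(c.acceptor_pos - candidate.acceptor_pos)
        if best is None or max(dd, da) < max(best[0], best[1]):
            best = (dd, da)
    if best is None:
        return False, None, None
    return (best[0] <= max_dist and best[1] <= max_dist), best[0], best[1]


def homopolymer_run(genome: Genome, junction: Junction, min_run: int = 5,
                    max_scan: int = 50):
    """Longest single-base run starting at the exonic base adjacent to either
    splice site; returns ``(run_length, flagged)`` with the max of the two ends.
    """
    seq = genome.sequences[junction.chrom]

    def run_leftward(pos):  # exon ends at pos (exclusive): scan pos-1, pos-2, ...
        if pos - 1 < 0:
            return 0
        base = seq[pos - 1]
        n = 0
        while pos - 1 - n >= 0 and n < max_scan and seq[pos - 1 - n] == base:
            n += 1
        return n

    def run_rightward(pos):  # exon starts at pos: scan pos, pos+1, ...
        if pos >= len(seq):
            return 0
        base = seq[pos]
        n = 0
        while pos + n < len(seq) and n < max_scan and seq[pos + n] == base:
            n += 1
        return n

    run = max(run_leftward(junction.start), run_rightward(junction.end))
    return run, run >= min_run


def gc_fraction(genome: Genome, junction: Junction, region: str = "intron",
                flank: int = 100) -> float:
    """(G+C)/(A+C+G+T) over the intron (default) or intron +/- flanks.

    N bases are excluded from the denominator; an all-N region is an error.
    """
    if region == "intron":
        s, e = junction.start, junction.end
    elif region == "intron_flanks":
        s = max(0, junction.start - flank)
        e = min(genome.length(junction.chrom), junction.end + flank)
    else:
        raise ValueError(f"unknown gc region {region!r}")
    seq = genome.fetch(junction.chrom, s, e)
    acgt = sum(1 for b in seq if b in "ACGT")
    if acgt == 0:
        raise ValueError("undefined GC fraction: region contains no A/C/G/T")
    return sum(1 for b in seq if b in "GC") / acgt


def partition_candidates(
    non_u2u12_candidates,
    canonical_set,
    genome: Genome,
    config: ArtifactConfig | None = None,
) -> list:
    """Partition non-U2/U12 candidates into artifact signatures.

    Near-canonical (both ends <= max_dist) splits on the flanking homopolymer
    run; isolated candidates with a direct repeat >= repeat_min OR GC >=
    gc_min are template-switch-like; the remainder is unexplained. The
    partition is exhaustive and mutually exclusive, and every measurement is
    reported raw so the partition can be re-derived.
    """
    config = config or ArtifactConfig()
    canonical_set = list(canonical_set)
    reports = []
    for j in non_u2u12_candidates:
        near, dd, da = near_canonical_partition(j, canonical_set, config.max_dist)
        run, run_flag = homopolymer_run(genome, j, config.min_run)
        repeat = enumerate_placements(genome, j).direct_repeat_length
        gc = gc_fraction(genome, j, config.gc_region)
        if near and run_flag:
            part = Partition.NEAR_CANONICAL_HOMOPOLYMER
        elif near:
            part = Partition.NEAR_CANONICAL_OTHER
        elif repeat >= config.repeat_min or gc >= config.gc_min:
            part = Partition.TEMPLATE_SWITCH_LIKE
        else:
            part = Partition.UNEXPLAINED
        reports.append(
            ArtifactReport(
                junction_key=j.key,
                partition=part,
                donor_distance=dd,
                acceptor_distance=da,
                homopolymer_run=run,
                direct_repeat_length=repeat,
                gc_fraction=gc,
            )
        )
    return reports
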