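"""Junction extraction from gapped alignments and the ab initio filter stack.

The detection contract mirrors a stringent RNA-seq junction survey: a gapped
alignment contributes evidence for an intron only when it is uniquely mapped
and anchored by >= 8 aligned nt on both sides (cDNA/EST evidence needs >= 15 nt
anchors with zero mismatches); a junction is *present* in one data source only
when at least three distinct supporting sequences back it; and a junction
enters the final set only when present in at least two independent sources.
Further filters remove non-canonical candidates that can be explained by
known SNPs/indels under the read footprint, by low-complexity sequence
(classic DUST triplet score), by user-supplied repeat intervals, or by
discordance between the maternal and paternal haplotypes of a diploid
genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from .core import (
    Genome,
    Junction,
    categorize_dinucleotides,
    extract_dinucleotides,
)

logger = logging.getLogger("ncsplice")

__all__ = [
    "GappedAlignmentRecord",
    "ExtractionConfig",
    "read_sam_records",
    "junctions_from_alignments",
    "merge_sources",
    "load_vcf_variants",
    "filter_variant_spanning",
    "dust_score",
    "filter_low_complexity",
    "filter_repeat_overlap",
    "diploid_concordance",
    "build_junction_library",
]


@dataclass
class GappedAlignmentRecord:
    """One gapped alignment: ordered blocks with per-block mismatch counts.

    ``blocks`` are ``((gstart, gend), (rstart, rend))`` pairs, genome-ascending
    and non-overlapping; the gap between consecutive blocks is a candidate
    intron. ``unique`` marks a uniquely mapping read (multi-mappers are
    ignored for junction evidence).
    """

    read_id: str
    read_sequence: str
    chrom: str
    strand: str
    blocks: list
    mismatches: list = field(default_factory=list)
    unique: bool = True

    def __post_init__(self):
        if not self.blocks:
            raise ValueError(f"record {self.read_id} has no block structure")
        if not self.mismatches:
            self.mismatches = [0] * len(self.blocks)
        prev_end = None
        for (gs, ge), (rs, re) in self.blocks:
            if ge <= gs or re <= rs:
                raise ValueError(f"record {self.read_id}: empty block")
            if prev_end is not None and gs < prev_end:
                raise ValueError(f"record {self.read_id}: negative or overlapping gap")
            prev_end = ge

    def gaps(self):
        """Yield (intron interval, left block index) for each skipped region."""
        for i in range(len(self.blocks) - 1):
            left_end = self.blocks[i][0][1]
            right_start = self.blocks[i + 1][0][0]
            if right_start > left_end:
                yield (left_end, right_start), i


@dataclass
class ExtractionConfig:
    """Thresholds of the ab initio detection stack (all in nt or counts)."""

    min_anchor_rnaseq: int = 8
    min_anchor_est: int = 15
    max_mismatches_est: int = 0
    min_support: int = 3
    min_sources: int = 2
    dust_threshold: float = 2.0
    dust_window: int = 64
    anchor_span: int = 25  # exonic footprint checked by the variant filter

    def __post_init__(self):
        for name in (
            "min_anchor_rnaseq",
            "min_anchor_est",
            "max_mismatches_est",
            "min_support",
            "min_sources",
            "dust_threshold",
            "dust_window",
            "anchor_span",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

def read_sam_records(path) -> Iterable[GappedAlignmentRecord]:
    """Stream gapped alignments from a SAM file (skipped-region gaps only).

    Uniqueness uses the NH tag when present (NH > 1 => multi-mapper);
    junction strand uses the XS tag when present, else the read's strand.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            blocks = []
            gpos = aln.reference_start
            rpos = 0
            for op, length in aln.cigartuples:
                if op == 0 or op == 7 or op == 8:  # M/=/X
                    blocks.append(((gpos, gpos + length), (rpos, rpos + length)))
                    gpos += length
                    rpos += length
                elif op == 1 or op == 4:  # I, S consume the read
                    rpos += length
                elif op == 2:  # D consumes the genome within a block
                    if blocks:
                        (gs, ge), rint = blocks[-1]
                        blocks[-1] = ((gs, ge + length), rint)
                    gpos += length
                elif op == 3:  # N: skipped region = candidate intron
                    gpos += length
            # merge adjacent M blocks not separated by N
            merged = []
            for (gs, ge), (rs, re) in blocks:
                if merged and merged[-1][0][1] == gs and merged[-1][1][1] == rs:
                    (pgs, _), (prs, _) = merged[-1]
                    merged[-1] = ((pgs, ge), (prs, re))
                else:
                    merged.append(((gs, ge), (rs, re)))
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
            strand = (
                aln.get_tag("XS")
                if aln.has_tag("XS")
                else ("-" if aln.is_reverse else "+")
            )
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            # without per-block mismatch tags, attribute all mismatches to
            # every block (conservative for the EST zero-mismatch rule)
            yield GappedAlignmentRecord(
                read_id=aln.query_name,
                read_sequence=aln.query_sequence or "",
                chrom=aln.reference_name,
                strand=strand,
                blocks=merged,
                mismatches=[nm] * len(merged),
                unique=(nh <= 1),
            )


def junctions_from_alignments(
    records: Iterable[GappedAlignmentRecord],
    config: ExtractionConfig,
    source_label: str,
    est_mode: bool = False,
) -> dict:
    """Collapse gapped alignments into junctions with distinct-sequence support.

    A record contributes support for a gap only if both flanking blocks are at
    least ``min_anchor`` nt long (read-interval length). In EST mode the anchor
    is >= ``min_anchor_est`` and both anchor blocks must carry at most
    ``max_mismatches_est`` mismatches. Support counts DISTINCT read sequences,
    never alignments, so PCR duplicates collapse to one.

    Returns ``{junction_key: Junction}`` with ``support[source_label]`` set.
    """
    min_anchor = config.min_anchor_est if est_mode else config.min_anchor_rnaseq
    seqs_per_junction: dict = {}
    for rec in records:
        if not rec.unique:
            continue
        for (gstart, gend), left_idx in rec.gaps():
            left_block = rec.blocks[left_idx]
            right_block = rec.blocks[left_idx + 1]
            left_anchor = left_block[1][1] - left_block[1][0]
            right_anchor = right_block[1][1] - right_block[1][0]
            if left_anchor < min_anchor or right_anchor < min_anchor:
                continue
            if est_mode and (
                rec.mismatches[left_idx] > config.max_mismatches_est
                or rec.mismatches[left_idx + 1] > config.max_mismatches_est
            ):
                continue
            key = (rec.chrom, gstart, gend, rec.strand)
            seqs_per_junction.setdefault(key, set()).add(rec.read_sequence)
    out = {}
    for (chrom, start, end, strand), seqs in seqs_per_junction.items():
        out[(chrom, start, end, strand)] = Junction(
            chrom, start, end, strand, support={source_label: len(seqs)}
        )
    return out


def merge_sources(
    per_source_junctions: Sequence[dict], config: ExtractionConfig
) -> dict:
    """Keep junctions present (>= min_support) in >= min_sources data sources.

    Presence is evaluated per source; support is merged, never summed across
    sources for the presence test, so two sources with 2 supporting sequences
    each do not add up to presence. Sources from one individual must be
    collapsed by the caller beforehand.
    """
    labels = []
    for jset in per_source_junctions:
        for j in jset.values():
            labels.extend(j.support.keys())
            break
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate source labels across inputs: {labels}")

    merged: dict = {}
    for jset in per_source_junctions:
        for key, j in jset.items():
            if key in merged:
                for src, n in j.support.items():
                    merged[key].support[src] = merged[key].support.get(src, 0) + n
                for smp, n in j.coverage.items():
                    merged[key].coverage[smp] = merged[key].coverage.get(smp, 0) + n
            else:
                merged[key] = Junction(
                    j.chrom, j.start, j.end, j.strand,
                    support=dict(j.support), coverage=dict(j.coverage),
                )
    return {
        key: j
        for key, j in merged.items()
        if sum(1 for n in j.support.values() if n >= config.min_support)
        >= config.min_sources
    }


# ---------------------------------------------------------------------------
# Variant (SNP/indel) filter
# ---------------------------------------------------------------------------

def load_vcf_variants(path) -> list:
    """Read SNP/indel intervals from a (plain-text) VCF.

    Returns ``(chrom, start, end)`` half-open reference intervals, one per
    ALT-bearing record (the REF footprint).
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append((rec.chrom, rec.start, rec.start + len(rec.ref)))
    return out


def _overlaps(intervals, chrom, start, end):
    return any(c == chrom and s < end and e > start for c, s, e in intervals)


def filter_variant_spanning(
    junctions: Iterable[Junction],
    variants: Sequence[tuple],
    genome: Genome,
    anchor_span: int = 25,
):
    """Discard non-canonical candidates whose footprint spans a known variant.

    The spanned footprint is the two terminal dinucleotides plus an exonic
    anchor window of ``anchor_span`` nt on each side of the intron. Canonical
    junctions pass untouched: a SNP under a GT-AG intron cannot have faked a
    non-canonical call.
    """
    kept, discarded = [], []
    for j in junctions:
        cat = categorize_dinucleotides(extract_dinucleotides(genome, j))
        if cat.is_canonical:
            kept.append(j)
            continue
        windows = [
            (j.start, j.start + 2),
            (j.end - 2, j.end),
            (max(0, j.start - anchor_span), j.start),
            (j.end, j.end + anchor_span),
        ]
        hit = any(_overlaps(variants, j.chrom, s, e) for s, e in windows)
        if hit:
            discarded.append((j, "variant_spanning"))
        else:
            kept.append(j)
    return kept, discarded


# ---------------------------------------------------------------------------
# DUST low-complexity filter
# ---------------------------------------------------------------------------

def dust_score(sequence: str, window: int = 64, word: int = 3) -> float:
    """Classic triplet-based low-complexity score.

    For every sliding window (length ``window``, step 1) count overlapping
    words of length ``word``; with word counts c_i over k word positions the
    window score is sum c_i (c_i - 1) / 2 divided by (k - 1). The sequence
    score is the maximum over windows. A homopolymer scores ~(k-1)/2, random
    sequence stays near 0.5.
    """
    seq = sequence.upper()
    if len(seq) < word:
        raise ValueError(f"sequence of length {len(seq)} shorter than word size {word}")
    best = 0.0
    n = len(seq)
    w = min(window, n)
    for ws in range(0, n - w + 1):
        counts: dict = {}
        k = 0
        for i in range(ws, ws + w - word + 1):
            t = seq[i : i + word]
            counts[t] = counts.get(t, 0) + 1
            k += 1
        if k > 1:
            s = sum(c * (c - 1) // 2 for c in counts.values()) / (k - 1)
            best = max(best, s)
    return best


def filter_low_complexity(
    junctions: Iterable[Junction], genome: Genome, config: ExtractionConfig
):
    """Discard junctions whose anchors or intron termini are low-complexity.

    Four regions are scored per junction (exonic anchor window and intronic
    terminus window at each end, each up to ``dust_window`` nt, truncated at
    chromosome/intron bounds); any region exceeding ``dust_threshold`` flags
    the junction.
    """
    w = config.dust_window
    kept, discarded = [], []
    for j in junctions:
        L = genome.length(j.chrom)
        regions = [
            (max(0, j.start - w), j.start),                  # 5' exonic anchor
            (j.end, min(L, j.end + w)),                      # 3' exonic anchor
            (j.start, min(j.end, j.start + w)),              # 5' intron terminus
            (max(j.start, j.end - w), j.end),                # 3' intron terminus
        ]
        flagged = False
        for s, e in regions:
            if e - s < 3:
                continue
            if dust_score(genome.fetch(j.chrom, s, e), window=w) > config.dust_threshold:
                flagged = True
                break
        if flagged:
            discarded.append((j, "low_complexity"))
        else:
            kept.append(j)
    return kept, discarded


def filter_repeat_overlap(junctions: Iterable[Junction], repeats: Sequence[tuple],
                          anchor_span: int = 25):
    """Discard junctions whose exonic anchors overlap user-supplied repeat
    intervals (``(chrom, start, end)`` BED-style, 0-based half-open)."""
    kept, discarded = [], []
    for j in junctions:
        windows = [(max(0, j.start - anchor_span), j.start + 2),
                   (j.end - 2, j.end + anchor_span)]
        if any(_overlaps(repeats, j.chrom, s, e) for s, e in windows):
            discarded.append((j, "repeat_overlap"))
        else:
            kept.append(j)
    return kept, discarded


# ---------------------------------------------------------------------------
# Diploid concordance
# ---------------------------------------------------------------------------

def diploid_concordance(
    maternal_junctions: dict,
    paternal_junctions: dict,
    coord_map: dict,
    min_support: int = 3,
):
    """Keep junctions found with >= min_support in BOTH haplotype alignments.

    ``coord_map`` maps ``(haplotype, chrom, start, end, strand)`` keys onto a
    common coordinate system (``(chrom, start, end, strand)``); it is supplied
    precomputed (TSV). Junctions either haplotype cannot map are excluded with
    reason "unmapped".
    """
    def translate(jset, hap):
        mapped, unmapped = {}, []
        for key, j in jset.items():
            common = coord_map.get((hap,) + key)
            if common is None:
                unmapped.append((j, "unmapped"))
            else:
                mapped[common] = j
        return mapped, unmapped

    mat, mat_un = translate(maternal_junctions, "maternal")
    pat, pat_un = translate(paternal_junctions, "paternal")
    kept = []
    for common, jm in mat.items():
        jp = pat.get(common)
        if jp is None:
            continue
        if jm.total_support() >= min_support and jp.total_support() >= min_support:
            chrom, start, end, strand = common
            support = dict(jm.support)
            for src, n in jp.support.items():
                support[src] = support.get(src, 0) + n
            kept.append(Junction(chrom, start, end, strand, support=support))
    return kept, mat_un + pat_un


def load_coord_map(path) -> dict:
    """Read a haplotype->common coordinate mapping TSV.

    Columns: haplotype, chrom, start, end, strand, common_chrom, common_start,
    common_end, common_strand.
    """
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out[(f[0], f[1], int(f[2]), int(f[3]), f[4])] = (
                f[5], int(f[6]), int(f[7]), f[8])
    return out


# ---------------------------------------------------------------------------
# Junction library
# ---------------------------------------------------------------------------

def build_junction_library(
    genome: Genome, junctions: Iterable[Junction], flank_len: int
) -> list:
    """Exon-exon library sequences for library-guided re-alignment.

    One record per junction: ``flank_len`` exonic nt upstream of the intron
    concatenated with ``flank_len`` exonic nt downstream, intron excised,
    genomic orientation. Junctions whose flanks would cross a chromosome end
    are skipped with a logged warning. Returns ``(name, sequence)`` pairs;
    names follow the track ID grammar.
    """
    from .trackio import junction_id

    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    records = []
    for j in junctions:
        L = genome.length(j.chrom)
        if j.start - flank_len < 0 or j.end + flank_len > L:
            logger.warning(
                "junction %s:%d-%d too close to chromosome edge; skipped",
                j.chrom, j.start, j.end,
            )
            continue
        seq = genome.fetch(j.chrom, j.start - flank_len, j.start) + genome.fetch(
            j.chrom, j.end, j.end + flank_len
        )
        records.append((junction_id(genome, j), seq))
    return records


def write_library_fasta(records, path):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
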