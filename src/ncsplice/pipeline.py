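"""End-to-end orchestration: alignments in, classified junction catalog out.

Stage order follows the detection protocol: per-source junction extraction
-> multi-source presence -> variant and low-complexity filters -> split into
canonical set and non-canonical candidates -> 1:20 minor-isoform filter ->
PWM training on the recovered canonical junctions -> direct-repeat placement
resolution (rescuing ambiguous canonical placements) -> scrambled-null
calibration and U2/U12 classification -> artifact partitioning of the
non-U2/U12 remainder -> A-to-I editing assessment of GT-AA / AT-AG
candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .altsplice import filter_minor_isoform
from .ambiguity import enumerate_placements, resolve_placement
from .artifacts import ArtifactConfig, partition_candidates
from .core import Genome, categorize_dinucleotides, extract_dinucleotides
from .editing import detect_editing, recode_edited
from .extraction import (
    ExtractionConfig,
    filter_low_complexity,
    filter_variant_spanning,
    junctions_from_alignments,
    merge_sources,
)
from .pwm import (
    ClassifierConfig,
    Classification,
    calibrate_null_threshold,
    canonical_site_index,
    classify,
    junction_windows,
    score_junction,
    shares_canonical_site,
    train_pwm_model,
)
from .simulate import dinucleotide_positions

logger = logging.getLogger("ncsplice")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    canonical: list = field(default_factory=list)    # (junction, subtype)
    rescued: list = field(default_factory=list)      # ambiguous-canonical rescues
    u2u12_like: list = field(default_factory=list)   # (junction, JunctionScore)
    non_u2u12: list = field(default_factory=list)    # (junction, JunctionScore)
    artifact_reports: list = field(default_factory=list)
    editing_reports: dict = field(default_factory=dict)  # key -> (pair, canonical)
    discarded: list = field(default_factory=list)    # (junction, reason)
    threshold: float = float("nan")
    pwm = None

    def classification_of(self, key) -> str | None:
        for j, _ in self.u2u12_like:
            if j.key == key:
                return Classification.U2U12_LIKE
        for j, _ in self.non_u2u12:
            if j.key == key:
                return Classification.NON_U2U12
        for j, _ in self.canonical:
            if j.key == key:
                return "CANONICAL"
        return None


def run_pipeline(
    genome: Genome,
    records_per_source: dict,
    variants=(),
    pileup: dict | None = None,
    extraction_config: ExtractionConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
    artifact_config: ArtifactConfig | None = None,
    minor_ratio: float = 1 / 20,
) -> PipelineResult:
    """Run the whole discovery pipeline on per-source gapped alignments.

    ``records_per_source`` maps source label -> iterable of
    GappedAlignmentRecord (each source also acts as a coverage sample).
    ``variants`` are (chrom, start, end) footprints or (chrom, pos, ref, alt)
    tuples; ``pileup`` maps (chrom, pos, strand) -> base counts for editing
    assessment.
    """
    xcfg = extraction_config or ExtractionConfig()
    ccfg = classifier_config or ClassifierConfig()
    acfg = artifact_config or ArtifactConfig()
    result = PipelineResult()

    # 1. per-source extraction; alignment counts double as sample coverage
    per_source = []
    for label, records in records_per_source.items():
        records = list(records)
        jset = junctions_from_alignments(records, xcfg, label)
        counts: dict = {}
        for rec in records:
            if not rec.unique:
                continue
            for (gs, ge), i in rec.gaps():
                lb, rb = rec.blocks[i], rec.blocks[i + 1]
                if (lb[1][1] - lb[1][0] >= xcfg.min_anchor_rnaseq
                        and rb[1][1] - rb[1][0] >= xcfg.min_anchor_rnaseq):
                    counts[(rec.chrom, gs, ge, rec.strand)] = (
                        counts.get((rec.chrom, gs, ge, rec.strand), 0) + 1
                    )
        for key, j in jset.items():
            j.coverage[label] = counts.get(key, 0)
        per_source.append(jset)

    # 2. presence in >= min_sources sources
    merged = merge_sources(per_source, xcfg)
    logger.info("merged junction set: %d", len(merged))

    # 3. variant filter (non-canonical candidates only)
    var_footprints = [
        (v[0], v[1], v[1] + (len(v[2]) if len(v) > 2 else 1)) if len(v) != 3 else v
        for v in variants
    ]
    kept, disc = filter_variant_spanning(
        merged.values(), var_footprints, genome, xcfg.anchor_span
    )
    result.discarded.extend(disc)

    # 4. DUST low-complexity filter
    kept, disc = filter_low_complexity(kept, genome, xcfg)
    result.discarded.extend(disc)

    # 5. canonical / candidate split
    canonical, candidates = [], []
    for j in kept:
        cat = categorize_dinucleotides(extract_dinucleotides(genome, j))
        if cat.is_canonical:
            canonical.append((j, cat.subtype))
        else:
            candidates.append(j)

    # 6. minor-isoform (1:20) filter over the full junction set
    surviving = set(
        j.key for j in filter_minor_isoform([j for j, _ in canonical] + candidates,
                                            minor_ratio)
    )
    canonical = [(j, st) for j, st in canonical if j.key in surviving]
    dropped = [j for j in candidates if j.key not in surviving]
    result.discarded.extend((j, "minor_isoform") for j in dropped)
    candidates = [j for j in candidates if j.key in surviving]

    # 7. PWM training on the recovered canonical set
    u2_train = [j for j, st in canonical if st in ("GT-AG", "GC-AG")]
    u12_train = [j for j, st in canonical if st == "AT-AC"]
    pwm = train_pwm_model(genome, u2_train, u12_train)
    result.pwm = pwm

    # 8. placement resolution (direct-repeat ambiguity)
    resolved = []
    for j in candidates:
        group = enumerate_placements(genome, j)
        chosen, rescued = resolve_placement(group, genome, pwm)
        if rescued:
            subtype = categorize_dinucleotides(
                extract_dinucleotides(genome, chosen)
            ).subtype
            canonical.append((chosen, subtype))
            result.rescued.append((chosen, subtype))
        else:
            resolved.append(chosen)

    # 9. null calibration and classification
    site_index = canonical_site_index([j for j, _ in canonical])
    if resolved:
        window_dicts = [junction_windows(genome, j, pwm.windows) for j in resolved]
        result.threshold = calibrate_null_threshold(pwm, window_dicts, ccfg)
        for j in resolved:
            score = score_junction(pwm, genome, j)
            label = classify(
                score,
                result.threshold,
                shares_canonical_site(j, site_index),
                j.intron_length,
                ccfg,
            )
            if label == Classification.U2U12_LIKE:
                result.u2u12_like.append((j, score))
            else:
                result.non_u2u12.append((j, score))

    # 10. artifact partition of the non-U2/U12 remainder
    result.artifact_reports = partition_candidates(
        [j for j, _ in result.non_u2u12], [j for j, _ in canonical], genome, acfg
    )

    # 11. editing assessment of GT-AA / AT-AG candidates
    if pileup:
        for j, _score in result.u2u12_like + result.non_u2u12:
            pair = extract_dinucleotides(genome, j)
            if (pair.donor, pair.acceptor) not in (("GT", "AA"), ("AT", "AG")):
                continue
            evidence = {}
            positions = dinucleotide_positions(j)
            for (side, idx), gpos in positions.items():
                mer = pair.donor if side == "donor" else pair.acceptor
                if mer[idx] != "A":
                    continue
                counts = pileup.get((j.chrom, gpos, j.strand))
                if counts is None:
                    continue
                evidence[(side, idx)] = detect_editing(j.chrom, gpos, "A", counts)
            if evidence:
                result.editing_reports[j.key] = recode_edited(pair, evidence)

    result.canonical = canonical
    return result
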