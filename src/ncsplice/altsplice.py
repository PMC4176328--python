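"""Alternative-splicing event typing and intron-usage (psi) quantification.

Junctions that share a splice site compete for the same transcripts; the
transitively closed set of junctions sharing donor or acceptor sites forms a
*splice-variant group*, the denominator of the intron usage fraction

    psi = coverage(junction) / sum coverage(group members)

estimated per sample with a 95% Wilson score interval on the underlying
binomial. Events are typed from group geometry: alternative 3' sites share a
donor, alternative 5' sites share an acceptor, a junction spanning the union
of two introns that flank an internal exon is the exon-skipping path (the
pair being the inclusion path), and an intron whose span retains unspliced
read depth is additionally reported as intron retention. Junctions detected
below a 1:20 coverage ratio against their group's predominant variant are
filtered out as quantitatively unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .core import Junction

logger = logging.getLogger("ncsplice")

__all__ = [
    "EventType",
    "SpliceVariantGroup",
    "AltSpliceEvent",
    "build_splice_variant_groups",
    "classify_events",
    "compute_psi",
    "filter_minor_isoform",
    "tissue_table",
]


class EventType:
    EXON_SKIPPING = "EXON_SKIPPING"
    EXON_INCLUSION = "EXON_INCLUSION"
    INTRON_RETENTION = "INTRON_RETENTION"
    ALT_5PRIME = "ALT_5PRIME"
    ALT_3PRIME = "ALT_3PRIME"
    CONSTITUTIVE = "CONSTITUTIVE"


@dataclass
class SpliceVariantGroup:
    """Junctions connected by shared donor/acceptor sites (transitive closure)."""

    members: list

    def total_coverage(self, sample: str | None = None) -> int:
        if sample is None:
            return sum(j.total_coverage() for j in self.members)
        return sum(j.coverage.get(sample, 0) for j in self.members)

    def predominant(self) -> Junction:
        return max(self.members, key=lambda j: j.total_coverage())


@dataclass
class AltSpliceEvent:
    junction_key: tuple
    event_types: list
    sample: str
    psi: float
    ci95: tuple

    def __post_init__(self):
        low, high = self.ci95
        assert low - 1e-12 <= self.psi <= high + 1e-12


def _sites(j: Junction):
    return (
        (j.chrom, j.strand, "donor", j.donor_pos),
        (j.chrom, j.strand, "acceptor", j.acceptor_pos),
    )


def build_splice_variant_groups(junctions) -> list:
    """Partition junctions into splice-variant groups by shared sites."""
    junctions = list(junctions)
    parent = list(range(len(junctions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    site_owner: dict = {}
    for i, j in enumerate(junctions):
        for site in _sites(j):
            if site in site_owner:
                union(site_owner[site], i)
            else:
                site_owner[site] = i
    comps: dict = {}
    for i in range(len(junctions)):
        comps.setdefault(find(i), []).append(junctions[i])
    return [SpliceVariantGroup(members=m) for m in comps.values()]


def classify_events(
    junctions,
    depth_track: dict | None = None,
    retention_fraction: float = 0.5,
    flank: int = 25,
) -> dict:
    """Assign event types to each placement-resolved, de-duplicated junction.

    Returns ``{junction_key: [event types]}``; a junction can carry several
    labels (a skipping junction also shares sites with its inclusion pair).
    ``depth_track`` maps chromosome -> per-base unspliced read depth array;
    without it intron-retention typing is skipped with a warning.
    """
    junctions = list(junctions)
    labels: dict = {j.key: [] for j in junctions}

    by_donor: dict = {}
    by_acceptor: dict = {}
    for j in junctions:
        d, a = _sites(j)
        by_donor.setdefault(d, []).append(j)
        by_acceptor.setdefault(a, []).append(j)
    for group in by_donor.values():
        if len({j.acceptor_pos for j in group}) > 1:
            for j in group:
                labels[j.key].append(EventType.ALT_3PRIME)
    for group in by_acceptor.values():
        if len({j.donor_pos for j in group}) > 1:
            for j in group:
                labels[j.key].append(EventType.ALT_5PRIME)

    # exon skipping: (s1,e1) + (s2,e2) with e1 < s2 flank an internal exon,
    # and (s1,e2) spans their union
    keys = {j.key for j in junctions}
    by_cs: dict = {}
    for j in junctions:
        by_cs.setdefault((j.chrom, j.strand), []).append(j)
    for (chrom, strand), group in by_cs.items():
        group = sorted(group, key=lambda j: (j.start, j.end))
        for a in group:
            for b in group:
                if a.end < b.start and (chrom, a.start, b.end, strand) in keys:
                    labels[(chrom, a.start, b.end, strand)].append(EventType.EXON_SKIPPING)
                    labels[a.key].append(EventType.EXON_INCLUSION)
                    labels[b.key].append(EventType.EXON_INCLUSION)

    if depth_track is None:
        logger.warning("no unspliced depth track: intron-retention typing skipped")
    else:
        for j in junctions:
            depth = depth_track.get(j.chrom)
            if depth is None:
                continue
            intron_depth = float(np.mean(depth[j.start : j.end]))
            lo = max(0, j.start - flank)
            hi = min(len(depth), j.end + flank)
            exon_depth = float(
                np.mean(np.concatenate([depth[lo : j.start], depth[j.end : hi]]))
            )
            if exon_depth > 0 and intron_depth >= retention_fraction * exon_depth:
                labels[j.key].append(EventType.INTRON_RETENTION)

    for key, lab in labels.items():
        # de-duplicate, keep first-seen order
        seen = []
        for x in lab:
            if x not in seen:
                seen.append(x)
        labels[key] = seen or [EventType.CONSTITUTIVE]
    return labels


def wilson_interval(successes: int, trials: int, alpha: float = 0.05) -> tuple:
    """95% Wilson score interval for a binomial proportion."""
    low, high = proportion_confint(successes, trials, alpha=alpha, method="wilson")
    return float(low), float(high)


def compute_psi(
    junction: Junction,
    group: SpliceVariantGroup,
    sample: str,
    event_types=None,
) -> AltSpliceEvent:
    """psi of one junction within its splice-variant group, for one sample."""
    total = group.total_coverage(sample)
    if total <= 0:
        raise ValueError(
            f"undefined psi: group coverage is zero in sample {sample!r}"
        )
    cov = junction.coverage.get(sample, 0)
    psi = cov / total
    return AltSpliceEvent(
        junction_key=junction.key,
        event_types=list(event_types or []),
        sample=sample,
        psi=psi,
        ci95=wilson_interval(cov, total),
    )


def filter_minor_isoform(junctions, ratio: float = 1 / 20) -> list:
    """Keep junctions with pooled coverage >= ratio x their group's predominant.

    The bound is inclusive (exactly 1:20 is kept) and the predominant member
    of every group always survives.
    """
    groups = build_splice_variant_groups(junctions)
    kept = []
    for g in groups:
        top = g.predominant().total_coverage()
        for j in g.members:
            if j.total_coverage() >= ratio * top:
                kept.append(j)
    return kept


def tissue_table(junction: Junction, group: SpliceVariantGroup, samples=None):
    """Per-sample psi with CIs plus pairwise CI non-overlap flags.

    Returns ``(rows, differential_pairs)`` where rows are
    ``(sample, psi, ci_low, ci_high)`` and differential_pairs holds the
    sample pairs whose 95% CIs do not overlap — the package's conservative
    notion of a tissue-differential splicing pattern.
    """
    if samples is None:
        samples = sorted(
            {s for j in group.members for s in j.coverage}
        )
    rows = []
    for sample in samples:
        if group.total_coverage(sample) <= 0:
            continue
        ev = compute_psi(junction, group, sample)
        rows.append((sample, ev.psi, ev.ci95[0], ev.ci95[1]))
    if len(rows) < 2:
        raise ValueError("tissue table needs >= 2 samples with defined psi")
    differential = []
    for i in range(len(rows)):
        for k in range(i + 1, len(rows)):
            _, _, lo1, hi1 = rows[i]
            _, _, lo2, hi2 = rows[k]
            if hi1 < lo2 or hi2 < lo1:
                differential.append((rows[i][0], rows[k][0]))
    return rows, differential
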