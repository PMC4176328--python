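"""Splicing-regulatory-element (SRE) hexamer density around splice sites.

SRE hexamers (ESE/ESS/ISE/ISS classes from fluorescence-activated screening,
supplied by the user as plain-text lists) are grouped by the identity they
promote: exon-identity elements (EIE = ESE + ISS) and intron-identity
elements (IIE = ISE + ESS). For a set of junctions, the positional density
of hexamer starts is computed in four 100-nt windows — 5' exonic, 5'
intronic, 3' intronic, 3' exonic, all in transcript orientation — as the
fraction of junctions carrying a set hexamer starting at each offset, then
smoothed with a 10-nt moving average. Density differences between two
junction groups are assessed with a Pearson chi-squared test on the 2x2
table of hexamer-start vs non-start position counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency

from .core import Genome, Junction, revcomp

__all__ = [
    "REGIONS",
    "HexamerSet",
    "DensityProfile",
    "load_hexamer_file",
    "region_sequences",
    "positional_density",
    "compare_density",
]

REGIONS = ("five_exonic", "five_intronic", "three_intronic", "three_exonic")

_IDENTITY = {"ESE": "EIE", "ISS": "EIE", "ISE": "IIE", "ESS": "IIE"}


@dataclass
class HexamerSet:
    hexamers: set
    sre_class: str  # ESE / ESS / ISE / ISS
    identity_group: str = field(init=False)

    def __post_init__(self):
        if self.sre_class not in _IDENTITY:
            raise ValueError(f"unknown SRE class {self.sre_class!r}")
        for h in self.hexamers:
            if len(h) != 6 or any(b not in "ACGT" for b in h):
                raise ValueError(f"invalid hexamer {h!r}")
        self.identity_group = _IDENTITY[self.sre_class]

    def __or__(self, other: "HexamerSet") -> set:
        return self.hexamers | other.hexamers


def load_hexamer_file(path) -> HexamerSet:
    """One 6-mer per line; the header line names the SRE class (e.g. '#ESE')."""
    hexamers = set()
    sre_class = None
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if not tok:
                continue
            if tok.lstrip("#") in _IDENTITY and sre_class is None:
                sre_class = tok.lstrip("#")
                continue
            hexamers.add(tok.upper())
    if sre_class is None:
        raise ValueError(f"{path}: no SRE class header (ESE/ESS/ISE/ISS)")
    return HexamerSet(hexamers=hexamers, sre_class=sre_class)


@dataclass
class DensityProfile:
    raw: dict        # region -> np.ndarray of per-offset densities in [0, 1]
    smoothed: dict   # region -> moving-average of raw
    window: int
    smooth: int
    junction_count: int


def region_sequences(
    genome: Genome, junction: Junction, window: int = 100, overhang: int = 5
) -> dict | None:
    """The four windows in transcript orientation, each extended by
    ``overhang`` nt on its transcript-3' side so hexamers starting at the
    last offset are complete. Returns None when any window would cross a
    chromosome end (such junctions are skipped with count adjustment)."""
    c, s, e = junction.chrom, junction.start, junction.end
    L = genome.length(c)
    if junction.strand == "+":
        spans = {
            "five_exonic": (s - window, s + overhang),
            "five_intronic": (s, s + window + overhang),
            "three_intronic": (e - window, e + overhang),
            "three_exonic": (e, e + window + overhang),
        }
        flip = False
    else:
        spans = {
            "five_exonic": (e - overhang, e + window),
            "five_intronic": (e - window - overhang, e),
            "three_intronic": (s - overhang, s + window),
            "three_exonic": (s - window - overhang, s),
        }
        flip = True
    out = {}
    for region, (a, b) in spans.items():
        if a < 0 or b > L:
            return None
        seq = genome.fetch(c, a, b)
        out[region] = revcomp(seq) if flip else seq
    return out


def _smooth(arr: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return arr.copy()
    kernel = np.ones(width) / width
    return np.convolve(arr, kernel, mode="same")


def positional_density(
    junctions, genome: Genome, hexamers, window: int = 100, smooth: int = 10
) -> DensityProfile:
    """Per-offset hexamer-start density over the four splice-site windows.

    Raw density at an offset = fraction of usable junctions with a set
    hexamer starting there (overlapping occurrences all count); smoothing is
    a centred ``smooth``-nt moving average. Offset 0 is the window base
    closest to the transcript 5' end of each window.
    """
    hexset = hexamers.hexamers if isinstance(hexamers, HexamerSet) else set(hexamers)
    usable = 0
    counts = {r: np.zeros(window) for r in REGIONS}
    for j in junctions:
        seqs = region_sequences(genome, j, window)
        if seqs is None:
            continue
        usable += 1
        for region, seq in seqs.items():
            for off in range(window):
                if seq[off : off + 6] in hexset:
                    counts[region][off] += 1
    if usable == 0:
        raise ValueError("no junction yields extractable windows")
    raw = {r: c / usable for r, c in counts.items()}
    return DensityProfile(
        raw=raw,
        smoothed={r: _smooth(v, smooth) for r, v in raw.items()},
        window=window,
        smooth=smooth,
        junction_count=usable,
    )


def compare_density(
    group_a, group_b, genome: Genome, hexamers, regions=REGIONS, window: int = 100
):
    """Pearson chi-squared homogeneity test of hexamer-start density.

    Builds the 2x2 table rows = groups, columns = (hexamer-start positions,
    non-start positions) summed over the requested regions, and applies the
    Pearson chi-squared test with 1 df and no continuity correction. Returns
    ``(statistic, p_value, table)``; a warning accompanies expected counts
    below 5.
    """
    import warnings

    if isinstance(regions, str):
        regions = (regions,)

    def tally(junctions):
        prof = positional_density(junctions, genome, hexamers, window, smooth=1)
        hits = sum(prof.raw[r].sum() * prof.junction_count for r in regions)
        total = prof.junction_count * window * len(regions)
        return hits, total - hits

    a_hit, a_miss = tally(group_a)
    b_hit, b_miss = tally(group_b)
    table = np.array([[a_hit, a_miss], [b_hit, b_miss]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("undefined statistic: zero marginal in the 2x2 table")
    if table[0].tolist() == table[1].tolist():
        return 0.0, 1.0, table  # identical rows: exactly homogeneous
    stat, p, _, expected = chi2_contingency(table, correction=False)
    if expected.min() < 5:
        warnings.warn("expected count < 5 in chi-squared table", stacklevel=2)
    return float(stat), float(p), table
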