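"""Genome-browser track writing, junction-table I/O and configuration.

Junctions are published as a BED12 track: each intron is drawn flanked by
two 8-nt exon blocks, named by an ID that encodes its splice-site
dinucleotides and read coverage — ``GA-AG[37]`` is a GA-AG intron covered by
37 reads. U2/U12-like junctions are coloured on a green ramp (lighter =
better consensus fit), non-U2/U12 junctions on a red ramp (lighter = worse
fit), canonical junctions in a fixed neutral grey. All coordinates are
0-based, BED convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re

import yaml

from .core import Genome, Junction, extract_dinucleotides

logger = logging.getLogger("ncsplice")

__all__ = [
    "junction_id",
    "parse_track_id",
    "write_track",
    "read_track",
    "write_junction_table",
    "read_junction_table",
    "load_config",
    "run_manifest",
]

EXON_BLOCK = 8  # nt of flanking exon drawn on each side of the intron

_ID_RE = re.compile(r"^([ACGTN]{2})[–-]([ACGTN]{2})\[(\d+)\]$")

_NEUTRAL = "120,120,120"
# 5 discrete bins per class; greens get lighter with HIGHER score,
# reds get lighter with LOWER score.
_GREEN_BINS = ["0,90,0", "0,130,0", "60,170,60", "120,210,120", "180,255,180"]
_RED_BINS = ["140,0,0", "180,40,40", "210,90,90", "235,140,140", "255,190,190"]


def junction_id(genome: Genome, junction: Junction) -> str:
    """``<donor>-<acceptor>[<total coverage>]`` (ASCII hyphen emitted)."""
    pair = extract_dinucleotides(genome, junction)
    return f"{pair.donor}-{pair.acceptor}[{junction.total_coverage()}]"


def parse_track_id(id_string: str) -> tuple:
    """Parse an ID back to (donor, acceptor, coverage).

    Accepts both the en-dash used in print and the ASCII hyphen.
    """
    m = _ID_RE.match(id_string)
    if m is None:
        raise ValueError(f"malformed junction ID {id_string!r}")
    return m.group(1), m.group(2), int(m.group(3))


def _bin5(score: float) -> int:
    """Map a 0-100 score onto 5 bins (0..4), 100 inclusive in the top bin."""
    return min(4, int(score // 20))


def _colour(label: str, score: float) -> str:
    if label == "CANONICAL":
        return _NEUTRAL
    if label == "U2U12_LIKE":
        return _GREEN_BINS[_bin5(score)]          # higher score -> lighter
    if label == "NON_U2U12":
        return _RED_BINS[4 - _bin5(score)]        # lower score -> lighter
    raise ValueError(f"unclassified junction label {label!r}")


def write_track(path, genome: Genome, records) -> None:
    """Write classified junctions as a sorted BED12 track.

    ``records`` is an iterable of ``(junction, label, score)`` with label in
    {CANONICAL, U2U12_LIKE, NON_U2U12} and score on the 0-100 PWM scale.
    """
    rows = []
    for junction, label, score in records:
        name = junction_id(genome, junction)
        chrom_start = junction.start - EXON_BLOCK
        chrom_end = junction.end + EXON_BLOCK
        if chrom_start < 0 or chrom_end > genome.length(junction.chrom):
            logger.warning("track record at chromosome edge skipped: %s", name)
            continue
        rows.append(
            (
                junction.chrom, chrom_start, chrom_end, name,
                int(round(score * 10)),  # BED score 0-1000
                junction.strand, chrom_start, chrom_end,
                _colour(label, score),
                2, f"{EXON_BLOCK},{EXON_BLOCK}",
                f"0,{EXON_BLOCK + junction.intron_length}",
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_track(path) -> list:
    """Re-ingest a written track: ``(junction, donor, acceptor, coverage)``."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start, chrom_end = f[0], int(f[1]), int(f[2])
            donor, acceptor, coverage = parse_track_id(f[3])
            j = Junction(
                chrom, chrom_start + EXON_BLOCK, chrom_end - EXON_BLOCK, f[5],
                coverage={"total": coverage},
            )
            out.append((j, donor, acceptor, coverage))
    return out


# ---------------------------------------------------------------------------
# Junction tables
# ---------------------------------------------------------------------------

def write_junction_table(path, junctions, extra_columns=None) -> None:
    """TSV: chrom, start, end, strand, support:<src>..., coverage:<sample>...

    ``extra_columns`` maps a column name to ``{junction_key: value}`` for
    optional annotations (resolved shift, rescue flag, class, score...).
    """
    junctions = list(junctions)
    extra_columns = extra_columns or {}
    sources = sorted({s for j in junctions for s in j.support})
    samples = sorted({s for j in junctions for s in j.coverage})
    header = (
        ["chrom", "start", "end", "strand"]
        + [f"support:{s}" for s in sources]
        + [f"coverage:{s}" for s in samples]
        + list(extra_columns)
    )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for j in sorted(junctions, key=lambda j: j.key):
            row = [j.chrom, str(j.start), str(j.end), j.strand]
            row += [str(j.support.get(s, 0)) for s in sources]
            row += [str(j.coverage.get(s, 0)) for s in samples]
            row += [str(extra_columns[c].get(j.key, "")) for c in extra_columns]
            fh.write("\t".join(row) + "\n")


def read_junction_table(path) -> list:
    junctions = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            support = {
                k.split(":", 1)[1]: int(v)
                for k, v in f.items()
                if k.startswith("support:")
            }
            coverage = {
                k.split(":", 1)[1]: int(v)
                for k, v in f.items()
                if k.startswith("coverage:")
            }
            junctions.append(
                Junction(
                    f["chrom"], int(f["start"]), int(f["end"]), f["strand"],
                    support=support, coverage=coverage,
                )
            )
    return junctions


# ---------------------------------------------------------------------------
# Configuration and run manifest
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def run_manifest(inputs: dict, config: dict, seed: int | None) -> dict:
    """Reproducibility record: inputs, config hash, seed, package version."""
    from . import __version__

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config_sha256": cfg_hash,
        "seed": seed,
        "version": __version__,
    }
    logger.info("run manifest: %s", json.dumps(manifest, sort_keys=True))
    return manifest
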