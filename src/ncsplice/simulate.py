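"""Synthetic genomes, junctions and read evidence with known truth.

The generator emulates the input structure the pipeline consumes: a genome
whose genes carry implanted introns of every class the method must tell
apart, gapped-alignment read evidence over them, a variant set, and pileup
counts at candidate editing positions.

Implant classes
---------------
``canonical``          GT-AG (mostly), GC-AG and AT-AC introns whose splice
                       sites are sampled from sharp consensus models — the
                       same frequency models the pipeline will re-estimate
                       as its PWMs (a self-consistent world, so recovery is
                       provable rather than probabilistic).
``u2u12_like``         one terminal dinucleotide deviates from canonical in
                       an otherwise consensus context >= 80 nt long; each is
                       an alternative 5'/3' variant sharing one splice site
                       with a canonical junction, as real non-canonical
                       sites usually do.
``template_switch``    a false junction with a planted direct repeat
                       (>= 7 nt) and GC-rich (~0.7) intron, random context.
``homopolymer``        a canonical junction plus a false junction shifted
                       <= 10 nt into it, with a >= 5-nt homopolymer run
                       adjacent to the false splice site.
``snp_confounded``     a non-canonical candidate whose donor dinucleotide
                       carries a reported SNP (emitted in the VCF).
``edited_gt_aa`` /     GT-AA or AT-AG termini in consensus context, with
``edited_at_ag``       A>G pileup evidence planted at the edited adenosine.

Every gene is checked, after assembly, to actually clear the orthogonal
filters its class assumes (intended dinucleotides, no ambiguous canonical
placement, DUST-clean windows, planted repeat/homopolymer lengths) and is
resampled otherwise, so truth labels are correct by construction. All
output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ambiguity import enumerate_placements
from .core import (
    Genome,
    Junction,
    categorize_dinucleotides,
    extract_dinucleotides,
    revcomp,
)
from .extraction import GappedAlignmentRecord, dust_score

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_reference",
    "simulate_evidence",
    "simulate_alt_event_junctions",
    "write_genome_fasta",
    "write_truth_tsv",
    "write_sam",
    "write_vcf",
    "write_pileup_tsv",
    "dinucleotide_positions",
]

_BASES = np.array(list("ACGT"))

# Consensus site sequences used to sample splice-site contexts. Layouts are
# (exonic, intronic) for donors and (intronic, exonic) for acceptors and
# match the default PWM windows. The terminal dinucleotide slots (marked by
# position) are overwritten with each implant's intended dinucleotide.
_CONSENSUS = {
    "u2_donor": ("CAG", "GTAAGT"),
    "u2_acceptor": ("TTTTTTTTTTTCAG", "GAA"),
    "u12_donor": ("CAG", "ATATCCTTT"),
    "u12_acceptor": ("CCTTAACTTTTCAC", "ATG"),
}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic world (all lengths in nt)."""

    seed: int = 0
    n_canonical: int = 100
    n_u2u12_like: int = 20
    n_template_switch: int = 10
    n_homopolymer: int = 10
    n_snp_confounded: int = 5
    n_edited_gt_aa: int = 2
    n_edited_at_ag: int = 2
    gc_ag_fraction: float = 0.08   # of canonical implants
    u12_fraction: float = 0.12     # AT-AC / U12-context canonical implants
    exon_len: tuple = (150, 250)
    intron_len: tuple = (160, 400)
    spacer: int = 400
    background_gc: float = 0.45
    consensus_dominance: float = 0.95  # per-position consensus probability
    ts_gc: float = 0.70
    ts_repeat: int = 7
    homopolymer_len: int = 6
    near_offset: int = 7           # shift of the homopolymer false junction
    alt_shift: int = 30            # alt-site offset of non-canonical variants
    nc_psi: float = 0.30           # planted usage of the non-canonical variant
    read_len: int = 50
    min_anchor: int = 10
    coverage_range: tuple = (30, 60)
    samples: tuple = ("tissueA", "tissueB")
    edited_counts: tuple = (12, 8)  # (A reads, G reads) at edited positions
    chrom_name: str = "chrS"
    add_decoys: bool = True

    def __post_init__(self):
        for name in (
            "n_canonical", "n_u2u12_like", "n_template_switch", "n_homopolymer",
            "n_snp_confounded", "n_edited_gt_aa", "n_edited_at_ag",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.intron_len[0] < 2 * self.alt_shift + 60:
            raise ValueError("intron_len too short for the alt-site layout")
        if self.exon_len[0] < self.read_len - self.min_anchor + 10:
            raise ValueError("exon_len too short for read anchors")


@dataclass
class TruthRecord:
    """Ground truth for one implanted junction."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    class_label: str     # canonical / u2u12_like / template_switch /
                         # homopolymer / snp_confounded / edited_gt_aa / edited_at_ag
    donor: str
    acceptor: str
    u12_type: bool = False
    psi: dict = field(default_factory=dict)        # sample -> planted psi
    coverage: dict = field(default_factory=dict)   # sample -> planted read count
    support: dict = field(default_factory=dict)    # sample -> distinct sequences
    edited_position: tuple | None = None           # (side, index, genomic pos)
    direct_repeat_length: int = 0
    homopolymer_run: int = 0
    partner_key: tuple | None = None               # canonical alt variant

    @property
    def key(self):
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def junction(self) -> Junction:
        return Junction(self.chrom, self.start, self.end, self.strand,
                        coverage=dict(self.coverage))


def dinucleotide_positions(junction: Junction) -> dict:
    """Genomic position of each terminal-dinucleotide base, transcript order."""
    s, e = junction.start, junction.end
    if junction.strand == "+":
        return {("donor", 0): s, ("donor", 1): s + 1,
                ("acceptor", 0): e - 2, ("acceptor", 1): e - 1}
    return {("donor", 0): e - 1, ("donor", 1): e - 2,
            ("acceptor", 0): s + 1, ("acceptor", 1): s}


# ---------------------------------------------------------------------------
# sequence sampling helpers (all operate in transcript sense)
# ---------------------------------------------------------------------------

def _random_seq(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _sample_consensus(rng, consensus: str, dominance: float) -> str:
    out = []
    off = (1 - dominance) / 3
    for b in consensus:
        probs = np.full(4, off)
        probs["ACGT".index(b)] = dominance
        out.append(rng.choice(_BASES, p=probs))
    return "".join(out)


def _splice_site_context(rng, model: str, side: str, dinuc: str, dominance: float):
    """(exonic part, intronic part) of one splice site, dinucleotide forced."""
    if side == "donor":
        ex, intr = _CONSENSUS[f"{model}_donor"]
        intr_s = _sample_consensus(rng, intr, dominance)
        intr_s = dinuc + intr_s[2:]
        return _sample_consensus(rng, ex, dominance), intr_s
    intr, ex = _CONSENSUS[f"{model}_acceptor"]
    intr_s = _sample_consensus(rng, intr, dominance)
    intr_s = intr_s[:-2] + dinuc
    return intr_s, _sample_consensus(rng, ex, dominance)


# ---------------------------------------------------------------------------
# gene builders: each returns (sense sequence, list of junction specs)
# ---------------------------------------------------------------------------
# A junction spec is a dict with sense-coordinate intron (istart, iend) plus
# truth metadata; coordinates are later mapped to genome coordinates (and
# mirrored for minus-strand genes).

def _build_intron(rng, cfg, model, donor_dinuc, acceptor_dinuc, length):
    """Intron sequence in sense orientation with consensus termini."""
    _, don_intr = _splice_site_context(rng, model, "donor", donor_dinuc,
                                       cfg.consensus_dominance)
    acc_intr, _ = _splice_site_context(rng, model, "acceptor", acceptor_dinuc,
                                       cfg.consensus_dominance)
    middle = _random_seq(rng, length - len(don_intr) - len(acc_intr),
                         cfg.background_gc)
    return don_intr + middle + acc_intr


def _gene_single_intron(rng, cfg, model, donor, acceptor, class_label,
                        u12_type=False):
    e1 = int(rng.integers(*cfg.exon_len))
    e2 = int(rng.integers(*cfg.exon_len))
    il = int(rng.integers(*cfg.intron_len))
    exon1 = _random_seq(rng, e1, cfg.background_gc)
    exon2 = _random_seq(rng, e2, cfg.background_gc)
    don_ex, _ = _splice_site_context(rng, model, "donor", donor,
                                     cfg.consensus_dominance)
    _, acc_ex = _splice_site_context(rng, model, "acceptor", acceptor,
                                     cfg.consensus_dominance)
    exon1 = exon1[: -len(don_ex)] + don_ex
    exon2 = acc_ex + exon2[len(acc_ex):]
    intron = _build_intron(rng, cfg, model, donor, acceptor, il)
    seq = exon1 + intron + exon2
    spec = dict(istart=e1, iend=e1 + il, class_label=class_label,
                donor=donor, acceptor=acceptor, u12_type=u12_type)
    return seq, [spec]


def _gene_alt_variant(rng, cfg, class_label, deviant_side, nc_donor, nc_acceptor,
                      edited=False):
    """Canonical intron plus a non-canonical alt-5'/3' variant inside it.

    The non-canonical variant shares one splice site with the canonical
    junction; its deviant splice site sits ``alt_shift`` nt inside the
    intron, in its own consensus context, so the two contexts never overlap.
    """
    seq, specs = _gene_single_intron(rng, cfg, "u2", "GT", "AG", "canonical")
    canon = specs[0]
    istart, iend = canon["istart"], canon["iend"]
    chars = list(seq)
    shift = cfg.alt_shift
    if deviant_side == "acceptor":
        # variant (istart, iend - shift): shared donor, deviant acceptor
        acc_intr, acc_ex = _splice_site_context(
            rng, "u2", "acceptor", nc_acceptor, cfg.consensus_dominance)
        pos = iend - shift - len(acc_intr)
        chars[pos : iend - shift + len(acc_ex)] = list(acc_intr + acc_ex)
        nc = dict(istart=istart, iend=iend - shift, class_label=class_label,
                  donor="GT", acceptor=nc_acceptor, u12_type=False)
    else:
        # variant (istart + shift, iend): deviant donor, shared acceptor
        don_ex, don_intr = _splice_site_context(
            rng, "u2", "donor", nc_donor, cfg.consensus_dominance)
        pos = istart + shift - len(don_ex)
        chars[pos : istart + shift + len(don_intr)] = list(don_ex + don_intr)
        nc = dict(istart=istart + shift, iend=iend, class_label=class_label,
                  donor=nc_donor, acceptor=nc_acceptor, u12_type=False)
    nc["edited"] = edited
    nc["partner"] = (istart, iend)
    canon["partner"] = (nc["istart"], nc["iend"])
    return "".join(chars), [canon, nc]


def _gene_template_switch(rng, cfg):
    """A false GC-rich junction flanked by a planted >= ts_repeat direct repeat."""
    e1 = int(rng.integers(*cfg.exon_len))
    e2 = int(rng.integers(*cfg.exon_len))
    il = int(rng.integers(*cfg.intron_len))
    exon1 = _random_seq(rng, e1, cfg.background_gc)
    exon2 = _random_seq(rng, e2, cfg.background_gc)
    intron = _random_seq(rng, il, cfg.ts_gc)
    # non-canonical termini, then copy the repeat across the junction:
    # seq[istart : istart+r] == seq[iend : iend+r]
    intron = "CC" + intron[2:-2] + "GG"
    seq = exon1 + intron + exon2
    chars = list(seq)
    istart, iend = e1, e1 + il
    repeat = chars[istart : istart + cfg.ts_repeat]
    chars[iend : iend + cfg.ts_repeat] = repeat
    spec = dict(istart=istart, iend=iend, class_label="template_switch",
                donor=None, acceptor=None, u12_type=False,
                repeat=cfg.ts_repeat)
    return "".join(chars), [spec]


def _gene_homopolymer(rng, cfg):
    """Canonical junction + false junction shifted into the intron, with a
    homopolymer run adjacent to the false donor."""
    seq, specs = _gene_single_intron(rng, cfg, "u2", "GT", "AG", "canonical")
    canon = specs[0]
    istart, iend = canon["istart"], canon["iend"]
    d = cfg.near_offset
    run = cfg.homopolymer_len
    chars = list(seq)
    # run of T just inside the canonical intron, ending right before the
    # false donor at istart + d (the false junction's exonic flank)
    chars[istart + d - run : istart + d] = ["T"] * run
    chars[istart + d : istart + d + 2] = ["C", "C"]      # false donor CC
    chars[iend + d - 2 : iend + d] = ["C", "C"]          # false acceptor CC
    false = dict(istart=istart + d, iend=iend + d, class_label="homopolymer",
                 donor="CC", acceptor="CC", u12_type=False, run=run,
                 partner=(istart, iend))
    canon["partner"] = (false["istart"], false["iend"])
    return "".join(chars), [canon, false]


# ---------------------------------------------------------------------------
# self-consistency guard
# ---------------------------------------------------------------------------

def _gene_ok(seq: str, specs, cfg) -> bool:
    """Does the assembled gene really carry its intended truth labels?"""
    g = Genome({"g": seq})
    for spec in specs:
        s, e = spec["istart"], spec["iend"]
        j = Junction("g", s, e, "+")
        pair = extract_dinucleotides(g, j)
        if spec["class_label"] == "template_switch":
            group = enumerate_placements(g, j)
            if group.direct_repeat_length < spec["repeat"]:
                return False
            for p in group.placements:
                if categorize_dinucleotides(extract_dinucleotides(g, p)).is_canonical:
                    return False
        else:
            if (pair.donor, pair.acceptor) != (spec["donor"], spec["acceptor"]):
                return False
            is_canon = categorize_dinucleotides(pair).is_canonical
            if is_canon != (spec["class_label"] == "canonical"):
                return False
            if not is_canon:
                # a non-canonical implant must have no ambiguous canonical
                # placement, or the resolver would (correctly) rescue it
                group = enumerate_placements(g, j)
                for p in group.placements:
                    if categorize_dinucleotides(
                        extract_dinucleotides(g, p)
                    ).is_canonical:
                        return False
        if spec["class_label"] == "homopolymer":
            # both placements of a near-canonical false junction score low,
            # so resolution must not be able to move it off its coordinates
            if seq[s] == seq[e] or seq[s - 1] == seq[e - 1]:
                return False
            base = seq[s - 1]
            n = 0
            while seq[s - 1 - n] == base:
                n += 1
            if n < spec["run"]:
                return False
        # DUST clearance with margin on the four filter regions
        for a, b in ((max(0, s - 64), s), (e, min(len(seq), e + 64)),
                     (s, min(e, s + 64)), (max(s, e - 64), e)):
            if b - a >= 3 and dust_score(seq[a:b]) > 1.8:
                return False
    return True


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig):
    """Build the genome and its truth table.

    Returns ``(genome, truths)``; writers below persist both as FASTA/TSV.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_gc = int(round(cfg.n_canonical * cfg.gc_ag_fraction))
    n_u12 = int(round(cfg.n_canonical * cfg.u12_fraction))
    n_gt = cfg.n_canonical - n_gc - n_u12
    if n_gt < 0:
        raise ValueError("gc_ag_fraction + u12_fraction exceed 1")

    plan = []
    plan += [("canonical_gt", None)] * n_gt
    plan += [("canonical_gc", None)] * n_gc
    plan += [("canonical_u12", None)] * n_u12
    # alternate deviant side; deviant dinucleotides cycle through observed
    # non-canonical pairs (one deviation from GT-AG)
    donors = ["GA", "GG", "CT", "TT"]
    acceptors = ["TG", "AA", "GG", "AT"]
    for i in range(cfg.n_u2u12_like):
        if i % 2 == 0:
            plan.append(("u2u12_like_acceptor", acceptors[i // 2 % len(acceptors)]))
        else:
            plan.append(("u2u12_like_donor", donors[i // 2 % len(donors)]))
    plan += [("template_switch", None)] * cfg.n_template_switch
    plan += [("homopolymer", None)] * cfg.n_homopolymer
    plan += [("snp_confounded", None)] * cfg.n_snp_confounded
    plan += [("edited_gt_aa", None)] * cfg.n_edited_gt_aa
    plan += [("edited_at_ag", None)] * cfg.n_edited_at_ag

    chrom_parts = [_random_seq(rng, 200, cfg.background_gc)]
    offset = 200
    truths: list = []
    for gene_idx, (kind, deviant) in enumerate(plan):
        for _attempt in range(200):
            if kind == "canonical_gt":
                seq, specs = _gene_single_intron(rng, cfg, "u2", "GT", "AG", "canonical")
            elif kind == "canonical_gc":
                seq, specs = _gene_single_intron(rng, cfg, "u2", "GC", "AG", "canonical")
            elif kind == "canonical_u12":
                seq, specs = _gene_single_intron(
                    rng, cfg, "u12", "AT", "AC", "canonical", u12_type=True)
            elif kind == "u2u12_like_acceptor":
                seq, specs = _gene_alt_variant(
                    rng, cfg, "u2u12_like", "acceptor", "GT", deviant)
            elif kind == "u2u12_like_donor":
                seq, specs = _gene_alt_variant(
                    rng, cfg, "u2u12_like", "donor", deviant, "AG")
            elif kind == "template_switch":
                seq, specs = _gene_template_switch(rng, cfg)
            elif kind == "homopolymer":
                seq, specs = _gene_homopolymer(rng, cfg)
            elif kind == "snp_confounded":
                seq, specs = _gene_alt_variant(
                    rng, cfg, "snp_confounded", "donor", "GA", "AG")
            elif kind == "edited_gt_aa":
                seq, specs = _gene_alt_variant(
                    rng, cfg, "edited_gt_aa", "acceptor", "GT", "AA", edited=True)
            elif kind == "edited_at_ag":
                seq, specs = _gene_alt_variant(
                    rng, cfg, "edited_at_ag", "donor", "AT", "AG", edited=True)
            else:  # pragma: no cover
                raise AssertionError(kind)
            if _gene_ok(seq, specs, cfg):
                break
        else:
            raise RuntimeError(f"could not assemble a consistent gene for {kind}")

        strand = "+" if rng.random() < 0.5 else "-"
        Lg = len(seq)
        genomic_seq = seq if strand == "+" else revcomp(seq)

        def to_genomic(istart, iend):
            if strand == "+":
                return offset + istart, offset + iend
            return offset + Lg - iend, offset + Lg - istart

        key_of = {}
        for spec in specs:
            gs, ge = to_genomic(spec["istart"], spec["iend"])
            key_of[(spec["istart"], spec["iend"])] = (cfg.chrom_name, gs, ge, strand)
        for spec in specs:
            gs, ge = to_genomic(spec["istart"], spec["iend"])
            pair_donor = spec["donor"]
            pair_acceptor = spec["acceptor"]
            truths.append(
                TruthRecord(
                    gene_id=f"gene{gene_idx}",
                    chrom=cfg.chrom_name, start=gs, end=ge, strand=strand,
                    class_label=spec["class_label"],
                    donor=pair_donor if pair_donor else "",
                    acceptor=pair_acceptor if pair_acceptor else "",
                    u12_type=spec.get("u12_type", False),
                    direct_repeat_length=spec.get("repeat", 0),
                    homopolymer_run=spec.get("run", 0),
                    partner_key=key_of.get(spec.get("partner")),
                )
            )
        chrom_parts.append(genomic_seq)
        chrom_parts.append(_random_seq(rng, cfg.spacer, cfg.background_gc))
        offset += Lg + cfg.spacer

    genome = Genome({cfg.chrom_name: "".join(chrom_parts)})
    # fill in dinucleotides the builders left empty (template switch)
    for t in truths:
        pair = extract_dinucleotides(genome, t.junction)
        t.donor, t.acceptor = pair.donor, pair.acceptor
    return genome, truths


# ---------------------------------------------------------------------------
# evidence simulation
# ---------------------------------------------------------------------------

def simulate_evidence(genome: Genome, truths, config: SimulationConfig):
    """Plant read coverage, alignments, variants and pileups.

    Returns ``(records_per_sample, variants, pileup)`` and fills each truth
    record's ``coverage``/``support``/``psi``/``edited_position`` in place.
    ``records_per_sample`` maps sample -> list of GappedAlignmentRecord;
    ``variants`` is a list of (chrom, pos0, ref, alt); ``pileup`` maps
    (chrom, pos0, strand) -> transcript-strand base counts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    by_key = {t.key: t for t in truths}
    records: dict = {s: [] for s in cfg.samples}
    variants: list = []
    pileup: dict = {}

    n_off = cfg.read_len - 2 * cfg.min_anchor + 1

    def emit_reads(t: TruthRecord, sample: str, count: int):
        out = 0
        for i in range(count):
            a = cfg.min_anchor + (i % n_off)
            pos = t.start - a
            seq = genome.fetch(t.chrom, pos, t.start) + genome.fetch(
                t.chrom, t.end, t.end + cfg.read_len - a)
            records[sample].append(
                GappedAlignmentRecord(
                    read_id=f"r_{t.chrom}_{t.start}_{t.end}_{sample}_{i}",
                    read_sequence=seq,
                    chrom=t.chrom,
                    strand=t.strand,
                    blocks=[((pos, t.start), (0, a)),
                            ((t.end, t.end + cfg.read_len - a),
                             (a, cfg.read_len))],
                )
            )
            out += 1
        return out

    for t in truths:
        # coverage: junctions paired into alt groups split a shared depth by
        # the planted psi; singletons take the full depth
        for sample in cfg.samples:
            if t.partner_key is not None:
                partner = by_key[t.partner_key]
                if t.class_label == "canonical":
                    continue  # handled from the non-canonical side
                depth = int(rng.integers(*cfg.coverage_range)) + 40
                nc_cov = max(1, int(round(cfg.nc_psi * depth)))
                t.coverage[sample] = nc_cov
                t.psi[sample] = nc_cov / depth
                partner.coverage[sample] = depth - nc_cov
                partner.psi[sample] = 1 - nc_cov / depth
            else:
                t.coverage[sample] = int(rng.integers(*cfg.coverage_range))
                t.psi[sample] = 1.0
    for t in truths:
        for sample in cfg.samples:
            count = t.coverage.get(sample, 0)
            emit_reads(t, sample, count)
            t.support[sample] = min(count, n_off)

    if cfg.add_decoys:
        # a multi-mapper and a short-anchor read over the first junctions:
        # neither may contribute support or coverage
        for t in truths[:5]:
            a = cfg.min_anchor
            pos = t.start - a
            seq = genome.fetch(t.chrom, pos, t.start) + genome.fetch(
                t.chrom, t.end, t.end + cfg.read_len - a)
            records[cfg.samples[0]].append(
                GappedAlignmentRecord(
                    read_id=f"decoy_multi_{t.start}", read_sequence=seq,
                    chrom=t.chrom, strand=t.strand,
                    blocks=[((pos, t.start), (0, a)),
                            ((t.end, t.end + cfg.read_len - a), (a, cfg.read_len))],
                    unique=False,
                )
            )
            short = 4
            pos = t.start - short
            seq = genome.fetch(t.chrom, pos, t.start) + genome.fetch(
                t.chrom, t.end, t.end + 30)
            records[cfg.samples[0]].append(
                GappedAlignmentRecord(
                    read_id=f"decoy_anchor_{t.start}", read_sequence=seq,
                    chrom=t.chrom, strand=t.strand,
                    blocks=[((pos, t.start), (0, short)),
                            ((t.end, t.end + 30), (short, short + 30))],
                )
            )

    for t in truths:
        if t.class_label == "snp_confounded":
            pos = dinucleotide_positions(t.junction)[("donor", 0)]
            ref = genome.fetch(t.chrom, pos, pos + 1)
            alt = "A" if ref != "A" else "G"
            variants.append((t.chrom, pos, ref, alt))
        if t.class_label in ("edited_gt_aa", "edited_at_ag"):
            side_idx = ("acceptor", 1) if t.class_label == "edited_gt_aa" else ("donor", 0)
            positions = dinucleotide_positions(t.junction)
            a_n, g_n = cfg.edited_counts
            for (side, idx), gpos in positions.items():
                base = genome.fetch(t.chrom, gpos, gpos + 1)
                tbase = base if t.strand == "+" else revcomp(base)
                counts = {"A": 0, "C": 0, "G": 0, "T": 0}
                if (side, idx) == side_idx:
                    counts["A"], counts["G"] = a_n, g_n
                else:
                    counts[tbase] = 20
                pileup[(t.chrom, gpos, t.strand)] = counts
            t.edited_position = side_idx + (positions[side_idx],)
    return records, variants, pileup


# ---------------------------------------------------------------------------
# event-geometry generator for alternative-splicing typing
# ---------------------------------------------------------------------------

def simulate_alt_event_junctions(
    n_skipping: int = 10, n_alt5: int = 10, n_constitutive: int = 10, seed: int = 0
):
    """Junction geometries with known event-type truth (no genome needed).

    Returns ``(junctions, truth)`` where truth maps junction key to the
    expected event label: each skipping triple contributes one EXON_SKIPPING
    span and two EXON_INCLUSION introns; alt-5' pairs share an acceptor; and
    constitutive introns are isolated.
    """
    rng = np.random.default_rng(seed)
    junctions, truth = [], {}
    pos = 1000
    for _ in range(n_skipping):
        s1 = pos
        e1 = s1 + int(rng.integers(100, 300))
        s2 = e1 + int(rng.integers(80, 150))      # internal exon
        e2 = s2 + int(rng.integers(100, 300))
        for (a, b), label in (
            ((s1, e1), "EXON_INCLUSION"),
            ((s2, e2), "EXON_INCLUSION"),
            ((s1, e2), "EXON_SKIPPING"),
        ):
            j = Junction("chrE", a, b, "+", coverage={"s": 10})
            junctions.append(j)
            truth[j.key] = label
        pos = e2 + 500
    for _ in range(n_alt5):
        e = pos + int(rng.integers(300, 500))
        s1 = pos
        s2 = pos + int(rng.integers(30, 100))
        for a in (s1, s2):
            j = Junction("chrE", a, e, "+", coverage={"s": 10})
            junctions.append(j)
            truth[j.key] = "ALT_5PRIME"
        pos = e + 500
    for _ in range(n_constitutive):
        s = pos
        e = s + int(rng.integers(100, 300))
        j = Junction("chrE", s, e, "+", coverage={"s": 10})
        junctions.append(j)
        truth[j.key] = "CONSTITUTIVE"
        pos = e + 500
    return junctions, truth


# ---------------------------------------------------------------------------
# writers (plain-text formats only)
# ---------------------------------------------------------------------------

def write_genome_fasta(path, genome: Genome):
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_tsv(path, truths):
    cols = [
        "gene_id", "chrom", "start", "end", "strand", "class_label", "donor",
        "acceptor", "u12_type", "direct_repeat_length", "homopolymer_run",
    ]
    with open(path, "w") as fh:
        samples = sorted({s for t in truths for s in t.coverage})
        header = cols + [f"coverage:{s}" for s in samples] + [f"psi:{s}" for s in samples]
        fh.write("\t".join(header) + "\n")
        for t in truths:
            row = [str(getattr(t, c)) for c in cols]
            row += [str(t.coverage.get(s, 0)) for s in samples]
            row += [f"{t.psi.get(s, 0):.6g}" for s in samples]
            fh.write("\t".join(row) + "\n")


def write_sam(path, genome: Genome, records):
    """Write gapped alignments as SAM with skipped-region (N) gaps."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.sequences.items()],
    }
    ref_ids = {name: i for i, name in enumerate(genome.sequences)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.read_sequence
            a.reference_id = ref_ids[rec.chrom]
            a.reference_start = rec.blocks[0][0][0]
            a.mapping_quality = 50
            cigar = []
            for i, ((gs, ge), (rs, re)) in enumerate(rec.blocks):
                if i > 0:
                    gap = gs - rec.blocks[i - 1][0][1]
                    cigar.append((3, gap))
                cigar.append((0, ge - gs))
            a.cigartuples = cigar
            a.flag = 0
            a.set_tag("NH", 1 if rec.unique else 2)
            a.set_tag("XS", rec.strand)
            out.write(a)


def write_vcf(path, genome: Genome, variants):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in sorted(variants, key=lambda v: (v[0], v[1])):
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_pileup_tsv(path, pileup):
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\tcountA\tcountC\tcountG\tcountT\n")
        for (chrom, pos, strand), c in sorted(pileup.items()):
            fh.write(
                f"{chrom}\t{pos}\t{strand}\t{c['A']}\t{c['C']}\t{c['G']}\t{c['T']}\n"
            )
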