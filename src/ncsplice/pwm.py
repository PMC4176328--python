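"""Position-weight-matrix splice-site scoring and U2/U12 classification.

Four site models are maintained — U2 donor, U2 acceptor, U12 donor,
U12 acceptor — each a per-position base-frequency matrix over a fixed
window around the exon/intron boundary. A window is scored by summing the
frequency of the observed base at every position and min-max normalising
to a 0-100 scale (the Shapiro-Senapathy convention): the consensus scores
100, the anti-consensus 0. A junction's score under one model is the mean
of its donor- and acceptor-site scores; its final score is the best of the
U2 and U12 models.

The decision threshold separating U2/U12-like from non-U2/U12 junctions is
calibrated from a scrambled-sequence null: every observed window is letter-
permuted (composition preserved) many times, the scrambled junctions are
scored, and the 95th percentile (nearest rank) of the pooled scores becomes
the threshold. Classification then applies, in order: introns shorter than
80 nt are non-U2/U12; scores above 70.00 are U2/U12-like directly; scores
between the calibrated threshold and 70.00 are U2/U12-like only when the
junction shares a splice site with a canonical junction; everything else is
non-U2/U12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Genome, Junction, revcomp

logger = logging.getLogger("ncsplice")

__all__ = [
    "SITE_KINDS",
    "DEFAULT_WINDOWS",
    "PWMModel",
    "ClassifierConfig",
    "JunctionScore",
    "Classification",
    "extract_site_window",
    "junction_windows",
    "build_pwm",
    "train_pwm_model",
    "score_site",
    "score_junction",
    "calibrate_null_threshold",
    "classify",
    "canonical_site_index",
    "shares_canonical_site",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: (model, side) keys for the four site matrices.
SITE_KINDS = ("u2_donor", "u2_acceptor", "u12_donor", "u12_acceptor")

#: Default window spec per site as (exonic nt, intronic nt). Donor windows
#: run exon->intron in transcript order, acceptor windows intron->exon.
DEFAULT_WINDOWS = {
    "u2_donor": (3, 6),
    "u2_acceptor": (3, 14),
    "u12_donor": (3, 9),
    "u12_acceptor": (3, 14),
}


@dataclass
class PWMModel:
    """The four trained site matrices plus their window specs.

    ``matrices[site]`` has shape (window_width, 4) with rows summing to 1;
    ``windows[site]`` is (exonic, intronic) and the width equals their sum.
    """

    matrices: dict
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    pseudocount: float = 1.0

    def __post_init__(self):
        for site, mat in self.matrices.items():
            mat = np.asarray(mat, dtype=float)
            self.matrices[site] = mat
            ex, intr = self.windows[site]
            if mat.shape != (ex + intr, 4):
                raise ValueError(
                    f"{site}: matrix shape {mat.shape} != window ({ex}+{intr}, 4)"
                )
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{site}: column frequencies do not sum to 1")

    def save_tsv(self, path):
        """Persist as TSV: site, offset, freqA, freqC, freqG, freqT."""
        with open(path, "w") as fh:
            fh.write("site\toffset\tfreqA\tfreqC\tfreqG\tfreqT\n")
            for site in SITE_KINDS:
                for off, row in enumerate(self.matrices[site]):
                    fh.write(
                        site + "\t" + str(off) + "\t"
                        + "\t".join(f"{v:.10g}" for v in row) + "\n"
                    )

    @classmethod
    def load_tsv(cls, path, windows=None):
        rows: dict = {s: [] for s in SITE_KINDS}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("site"):
                raise ValueError("PWM TSV missing header")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rows[f[0]].append([float(x) for x in f[2:6]])
        mats = {s: np.array(v) for s, v in rows.items()}
        if windows is None:
            windows = {}
            for s, m in mats.items():
                ex = DEFAULT_WINDOWS[s][0]
                windows[s] = (ex, m.shape[0] - ex)
        return cls(matrices=mats, windows=windows)


@dataclass
class ClassifierConfig:
    """Fixed rule constants plus the null-calibration settings."""

    direct_threshold: float = 70.00
    null_scrambles: int = 10000
    null_percentile: float = 95.0
    min_intron: int = 80
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.direct_threshold <= 100):
            raise ValueError("direct_threshold must be in [0, 100]")
        if not (0 <= self.null_percentile <= 100):
            raise ValueError("null_percentile must be in [0, 100]")


@dataclass(frozen=True)
class JunctionScore:
    u2_score: float
    u12_score: float

    @property
    def final_score(self) -> float:
        return max(self.u2_score, self.u12_score)

    @property
    def best_model(self) -> str:
        # ties break toward the (far more common) U2 model
        return "U2" if self.u2_score >= self.u12_score else "U12"


class Classification:
    U2U12_LIKE = "U2U12_LIKE"
    NON_U2U12 = "NON_U2U12"


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_site_window(
    genome: Genome, junction: Junction, side: str, exonic: int, intronic: int
) -> str:
    """Sequence window around one splice site, transcript orientation.

    ``side`` is "donor" or "acceptor". Donor windows are exon->intron
    (``exonic`` exonic nt then ``intronic`` intronic nt); acceptor windows
    are intron->exon (``intronic`` then ``exonic``).
    """
    c, s, e = junction.chrom, junction.start, junction.end
    if junction.strand == "+":
        if side == "donor":
            return genome.fetch(c, s - exonic, s + intronic)
        return genome.fetch(c, e - intronic, e + exonic)
    if side == "donor":
        return revcomp(genome.fetch(c, e - intronic, e + exonic))
    return revcomp(genome.fetch(c, s - exonic, s + intronic))


def junction_windows(genome: Genome, junction: Junction, windows=None) -> dict:
    """All four site windows of a junction, keyed like the matrices."""
    windows = windows or DEFAULT_WINDOWS
    out = {}
    for site, (ex, intr) in windows.items():
        side = "donor" if site.endswith("donor") else "acceptor"
        out[site] = extract_site_window(genome, junction, side, ex, intr)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def build_pwm(training_windows, pseudocount: float = 1.0) -> np.ndarray:
    """Column frequencies (count + pseudocount) / (n + 4*pseudocount).

    ``training_windows`` are equal-length sequences over A/C/G/T; at least
    10 are required for a usable matrix.
    """
    seqs = list(training_windows)
    if len(seqs) < 10:
        raise ValueError(
            f"need >= 10 training windows, got {len(seqs)}"
        )
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("training windows differ in length")
    counts = np.zeros((width, 4))
    for s in seqs:
        for i, b in enumerate(s.upper()):
            if b in _BASE_INDEX:
                counts[i, _BASE_INDEX[b]] += 1
    n = len(seqs)
    return (counts + pseudocount) / (n + 4 * pseudocount)


def train_pwm_model(
    genome: Genome,
    u2_junctions,
    u12_junctions,
    windows=None,
    pseudocount: float = 1.0,
) -> PWMModel:
    """Train the four site matrices from canonical junction sets.

    ``u2_junctions`` are GT-AG (optionally GC-AG) junctions; ``u12_junctions``
    are junctions the caller flags as U12-type (AT-AC or U12-context GT-AG).
    """
    windows = dict(windows or DEFAULT_WINDOWS)
    mats = {}
    for site in SITE_KINDS:
        pool = u2_junctions if site.startswith("u2") else u12_junctions
        ex, intr = windows[site]
        side = "donor" if site.endswith("donor") else "acceptor"
        seqs = [extract_site_window(genome, j, side, ex, intr) for j in pool]
        mats[site] = build_pwm(seqs, pseudocount)
    return PWMModel(matrices=mats, windows=windows, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_site(matrix: np.ndarray, window_sequence: str) -> float:
    """Min-max normalised frequency-sum score on the 0-100 scale.

    raw = sum over positions of freq(observed base); the score maps raw
    linearly so the column-wise maxima give 100 and the minima 0. An N
    contributes the column minimum (most pessimistic real base).
    """
    matrix = np.asarray(matrix)
    if len(window_sequence) != matrix.shape[0]:
        raise ValueError(
            f"window length {len(window_sequence)} != matrix width {matrix.shape[0]}"
        )
    col_min = matrix.min(axis=1)
    raw = 0.0
    for i, b in enumerate(window_sequence.upper()):
        raw += matrix[i, _BASE_INDEX[b]] if b in _BASE_INDEX else col_min[i]
    raw_min = col_min.sum()
    raw_max = matrix.max(axis=1).sum()
    if raw_max == raw_min:  # degenerate flat matrix
        return 100.0
    return 100.0 * (raw - raw_min) / (raw_max - raw_min)


def score_junction(pwm: PWMModel, genome: Genome, junction: Junction) -> JunctionScore:
    """Mean of donor and acceptor site scores per model; best model wins."""
    wins = junction_windows(genome, junction, pwm.windows)
    u2 = 0.5 * (
        score_site(pwm.matrices["u2_donor"], wins["u2_donor"])
        + score_site(pwm.matrices["u2_acceptor"], wins["u2_acceptor"])
    )
    u12 = 0.5 * (
        score_site(pwm.matrices["u12_donor"], wins["u12_donor"])
        + score_site(pwm.matrices["u12_acceptor"], wins["u12_acceptor"])
    )
    return JunctionScore(u2_score=u2, u12_score=u12)


def _score_window_dict(pwm: PWMModel, wins: dict) -> float:
    u2 = 0.5 * (
        score_site(pwm.matrices["u2_donor"], wins["u2_donor"])
        + score_site(pwm.matrices["u2_acceptor"], wins["u2_acceptor"])
    )
    u12 = 0.5 * (
        score_site(pwm.matrices["u12_donor"], wins["u12_donor"])
        + score_site(pwm.matrices["u12_acceptor"], wins["u12_acceptor"])
    )
    return max(u2, u12)


def nearest_rank_percentile(values, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    vals = sorted(values)
    if not vals:
        raise ValueError("empty value pool")
    rank = int(np.ceil(percentile / 100.0 * len(vals)))
    rank = max(1, min(rank, len(vals)))
    return vals[rank - 1]


def calibrate_null_threshold(
    pwm: PWMModel, junction_window_dicts, config: ClassifierConfig
) -> float:
    """Scrambled-sequence null threshold.

    For each scramble iteration, every site window of every junction is
    letter-permuted uniformly at random (base composition preserved), the
    scrambled junction is rescored, and all scores are pooled; the threshold
    is the nearest-rank ``null_percentile`` of the pool. Deterministic given
    ``config.seed``.
    """
    dicts = list(junction_window_dicts)
    if not dicts:
        raise ValueError("no junction windows to calibrate from")
    rng = np.random.default_rng(config.seed)
    # number of iterations so the pool reaches ~null_scrambles scores
    iters = max(1, int(np.ceil(config.null_scrambles / len(dicts))))
    pool = []
    for _ in range(iters):
        for wins in dicts:
            scrambled = {}
            for site, seq in wins.items():
                letters = np.array(list(seq))
                scrambled[site] = "".join(letters[rng.permutation(len(letters))])
            pool.append(_score_window_dict(pwm, scrambled))
    return nearest_rank_percentile(pool, config.null_percentile)


# ---------------------------------------------------------------------------
# Classification rule
# ---------------------------------------------------------------------------

def classify(
    junction_score: JunctionScore,
    threshold: float,
    shares_canonical_site: bool,
    intron_len: int,
    config: ClassifierConfig | None = None,
) -> str:
    """Apply the U2/U12-like decision rule (order matters).

    1. intron shorter than ``min_intron`` (80 nt) -> NON_U2U12;
    2. final score above ``direct_threshold`` (70.00) -> U2U12_LIKE;
    3. score in [threshold, 70.00] and sharing a splice site with a
       canonical junction -> U2U12_LIKE;
    4. otherwise NON_U2U12.
    """
    config = config or ClassifierConfig()
    if threshold > config.direct_threshold:
        logger.warning(
            "calibrated null threshold %.2f exceeds the direct threshold %.2f; "
            "the shared-site rescue band is empty",
            threshold, config.direct_threshold,
        )
    score = junction_score.final_score
    if intron_len < config.min_intron:
        return Classification.NON_U2U12
    if score > config.direct_threshold:
        return Classification.U2U12_LIKE
    if threshold <= score <= config.direct_threshold and shares_canonical_site:
        return Classification.U2U12_LIKE
    return Classification.NON_U2U12


# ---------------------------------------------------------------------------
# Shared-site lookup
# ---------------------------------------------------------------------------

def canonical_site_index(canonical_junctions) -> set:
    """Set of (chrom, strand, side, position) splice sites of a canonical set."""
    sites = set()
    for j in canonical_junctions:
        sites.add((j.chrom, j.strand, "donor", j.donor_pos))
        sites.add((j.chrom, j.strand, "acceptor", j.acceptor_pos))
    return sites


def shares_canonical_site(junction: Junction, site_index: set) -> bool:
    return (
        (junction.chrom, junction.strand, "donor", junction.donor_pos) in site_index
        or (junction.chrom, junction.strand, "acceptor", junction.acceptor_pos)
        in site_index
    )
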