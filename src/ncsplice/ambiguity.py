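"""Direct-repeat placement ambiguity: enumeration and resolution.

Identical sequence at the two flanks of an intron (a direct repeat) makes
several intron placements excise to the same mature transcript, so the
aligner's choice among them is arbitrary. Each equivalent placement can
expose different terminal dinucleotides, which is a classic source of false
non-canonical calls. Here every equivalent placement is enumerated; if any
of them is canonical the junction is *rescued* (re-assigned to the best
canonical placement and excluded from the non-canonical set), otherwise the
placement with the best PWM fit is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import Genome, Junction, categorize_dinucleotides, extract_dinucleotides
from .pwm import PWMModel, score_junction

logger = logging.getLogger("ncsplice")

__all__ = ["AmbiguityGroup", "enumerate_placements", "resolve_placement"]


@dataclass
class AmbiguityGroup:
    """All coordinate placements of one junction with an identical spliced product."""

    placements: list  # Junction objects, ascending by shift
    shifts: list      # signed shift of each placement relative to the input
    left_shift: int
    right_shift: int

    @property
    def direct_repeat_length(self) -> int:
        return self.left_shift + self.right_shift

    def __post_init__(self):
        if self.placements:
            assert len(self.placements) == self.left_shift + self.right_shift + 1
            lengths = {j.intron_length for j in self.placements}
            assert len(lengths) == 1, "placements must share intron length"


def enumerate_placements(
    genome: Genome, junction: Junction, max_shift: int = 30
) -> AmbiguityGroup:
    """Enumerate every intron placement equivalent under the direct repeat.

    A shift of +1 is valid when genome[start] == genome[end] (the intron's
    first base equals the first base after it), and so on cumulatively; a
    shift of -1 when genome[start-1] == genome[end-1]. The search is capped
    at ``max_shift`` in each direction (longer repeats are template-switch
    territory) and truncated, with a note, at chromosome bounds.
    """
    seq = genome.sequences[junction.chrom]
    L = len(seq)
    s, e = junction.start, junction.end

    right = 0
    while right < max_shift:
        if e + right >= L:
            logger.info("placement shift truncated at chromosome end (%s)", junction.chrom)
            break
        if seq[s + right] != seq[e + right]:
            break
        right += 1
    left = 0
    while left < max_shift:
        if s - left - 1 < 0:
            logger.info("placement shift truncated at chromosome start (%s)", junction.chrom)
            break
        if seq[s - left - 1] != seq[e - left - 1]:
            break
        left += 1

    placements, shifts = [], []
    for sh in range(-left, right + 1):
        placements.append(
            Junction(
                junction.chrom, s + sh, e + sh, junction.strand,
                support=dict(junction.support), coverage=dict(junction.coverage),
            )
        )
        shifts.append(sh)
    return AmbiguityGroup(placements=placements, shifts=shifts,
                          left_shift=left, right_shift=right)


def resolve_placement(
    group: AmbiguityGroup, genome: Genome, pwm: PWMModel
) -> tuple:
    """Pick one placement: canonical placements win, else the best PWM fit.

    Returns ``(chosen_junction, rescued_canonical)``. When any placement has
    canonical dinucleotides the highest-scoring canonical placement is chosen
    and ``rescued_canonical`` is True — the junction must then not be reported
    as non-canonical. Otherwise the placement maximising the final PWM score
    wins; ties break toward the smallest absolute shift, then leftmost. The
    result does not depend on the order of the input placements.
    """
    if not group.placements:
        raise ValueError("empty ambiguity group")

    entries = []
    for j, sh in zip(group.placements, group.shifts):
        canonical = categorize_dinucleotides(
            extract_dinucleotides(genome, j)
        ).is_canonical
        score = score_junction(pwm, genome, j).final_score
        entries.append((j, sh, canonical, score))

    canon = [t for t in entries if t[2]]
    pool = canon if canon else entries
    # maximise score; ties -> smallest |shift|, then leftmost (smallest shift)
    best = max(pool, key=lambda t: (t[3], -abs(t[1]), -t[1]))
    return best[0], bool(canon)
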