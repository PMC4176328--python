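# Methods

This note documents the models, rules and numerical choices behind
`ncsplice`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## Coordinates and junction identity

Every interval is 0-based, half-open, on the reference forward strand; a
junction is its intron, `start` being the first and `end − 1` the last
intronic base. Donor/acceptor dinucleotides are always reported in
transcript orientation (reverse-complemented on the minus strand). Intron
length down to 1 nt is representable because the upstream aligner setting
this package consumes permits it; dinucleotide extraction naturally
requires ≥ 2 nt. Out-of-bounds genome access is an error, never a silent
clip — coordinate bugs should crash, not corrupt. Lowercase (soft-masked)
bases are uppercased on load; masking is not used as a filter, since
low-complexity and repeat filtering are explicit pipeline stages.

Canonical means GT–AG, GC–AG or AT–AC, exactly; any N in a terminal
dinucleotide makes a junction a non-canonical *candidate* with an
ambiguous-base flag, never canonical — fabricating canonical calls over
assembly gaps is the worse error.

## Evidence model

Support is counted in **distinct read sequences**, not alignments or read
IDs, so PCR duplicates collapse; presence in a data source requires ≥ 3
distinct sequences and a junction must be present in ≥ 2 sources (sources
from one individual should be collapsed by the caller first). Anchors — the
aligned block on each side of the gap — must be ≥ 8 nt (RNA-seq) or ≥ 15 nt
with zero mismatches (cDNA/EST). Merging never sums support across sources
for the presence test: 2 + 2 is not presence.

The variant filter discards a non-canonical candidate when a SNP or indel
overlaps its terminal dinucleotides or a 25-nt exonic anchor window on
either side; 25 nt matches the mismatch window of the upstream aligner
configuration and stands in for the read footprint, which is not otherwise
recorded. Canonical junctions pass untouched — a variant cannot have faked
a canonical call into a non-canonical one.

DUST low complexity: the classic triplet score, window 64, word 3,
threshold 2.0 (the classic defaults; the method names DUST without
parameters). A window score is Σ c(c−1)/2 over triplet counts divided by
(k − 1) triplet positions; the four regions checked per junction are the
exonic anchor window and intronic terminus window at each end.

Diploid concordance keeps a junction only when the identical common-system
interval reaches support ≥ 3 in **both** haplotype alignments (the stricter
reading of "coincident"); coordinate translation between haplotypes is
consumed as a precomputed table, as is cross-species mapping — chain/liftover
computation is out of scope.

## PWM scoring and classification

Four matrices: U2 donor (3 exonic + 6 intronic nt), U2 acceptor (14
intronic + 3 exonic), U12 donor (3 + 9), U12 acceptor (14 + 3). The window
sizes are configurable; the defaults cover the core donor consensus and the
acceptor polypyrimidine/branch-adjacent region without modelling the branch
point explicitly. Column frequencies are (count + pseudocount) /
(n + 4·pseudocount), pseudocount 1; ≥ 10 training junctions per site are
required. Matrices are trained from user-supplied canonical junctions
(GT–AG/GC–AG for U2, caller-flagged U12-type for U12) rather than shipping
published matrix values.

A window scores 100·(raw − min)/(max − min), raw being the sum of observed
base frequencies — the standard Shapiro–Senapathy 0–100 convention, which a
fixed 70.00 cutoff presupposes. The junction score is the **mean** of donor
and acceptor site scores, then the **max** over the U2 and U12 models
(ties to U2, the overwhelmingly more common type). The combiner is a design
choice: a single per-junction score is required and the mean penalises a
junction that fits on one side only; sensitivity to this choice can be
probed by scoring sites individually through the public `score_site`.

The null: every observed site window is letter-permuted uniformly
(composition preserved — scrambling within the window, not across columns,
since column shuffling would retain positional information), the scrambled
junctions are rescored, and the threshold is the nearest-rank 95th
percentile of the pooled scores. Nearest rank avoids interpolation
ambiguity and makes the threshold an actual pool member. Classification
order: (1) intron < 80 nt → non-U2/U12; (2) score > 70.00 → U2/U12-like;
(3) threshold ≤ score ≤ 70.00 and shares a donor or acceptor with a
canonical junction → U2/U12-like; (4) otherwise non-U2/U12. The band in
rule 3 presumes threshold < 70; should a calibration exceed 70 the band is
empty and a warning is logged rather than guessing a different ordering.

## Placement ambiguity

A direct repeat of length r at the junction yields r + 1 placements with
identical mature transcripts (shift validity is the cumulative condition
`genome[start+i] == genome[end+i]`, and mirrored leftward). Enumeration is
capped at ±30 nt — repeats beyond that are template-switch territory, which
the artifact module measures on the same scale. Resolution: any canonical
placement wins (the junction is *rescued* and re-assigned canonical rather
than deleted, preserving the evidence); otherwise the placement with the
best PWM score, ties to the smallest absolute shift and then leftmost — a
deterministic, documented tie-break, since score ties have no biological
ordering.

## Alternative splicing

The ψ denominator is the transitively closed group of junctions sharing a
donor or acceptor site — the smallest set within which junction coverages
compete for the same transcripts. ψ intervals are 95% Wilson score
intervals (better behaviour at extreme ψ than the normal approximation,
still standard; implemented via statsmodels, cross-checked against the
closed form in the tests). The 1:20 minor-isoform filter is inclusive
(exactly 1:20 survives) and uses coverage pooled over samples, so a
junction reliably seen in one tissue is not discarded for being absent in
another. Intron retention requires an optional unspliced-depth track
(default rule: mean intronic depth ≥ 0.5 × mean flanking exonic depth);
without a track, retention typing is skipped with a warning. Tissue
comparisons report per-sample ψ with CIs and flag CI non-overlap — no
stronger differential-splicing statistic is attempted.

## Artifact partition

Near-canonical means |Δdonor| ≤ 10 **and** |Δacceptor| ≤ 10 nt to some
canonical junction, measured between like ends on the same strand.
Homopolymer runs are counted from the exonic base immediately adjacent to
each splice site; ≥ 5 nt flags the candidate. Template-switch-like means
direct repeat ≥ 6 nt **or** intronic %GC ≥ 0.6; both cutoffs are exposed in
configuration and every raw measurement is reported alongside the
partition, because the underlying evidence is a distribution shift, not a
sharp boundary. %GC defaults to the intron (configurable to intron ±
100-nt flanks); N bases are excluded from the denominator.

## RNA editing

Only the four terminal-dinucleotide positions are assessed. Evidence
passes with G-count ≥ 3 and G/(A+G) ≥ 0.2 at a transcript-strand adenosine
(minus-strand genomic T>C must be translated by the caller; the packaged
pileup format is already transcript-strand). The thresholds are defaults
chosen to demand consistent, multi-read mismatch evidence while retaining
partially edited sites; both are configurable. Recoding substitutes A→G
only and is idempotent. The packaged table of seven published human edited
sites (four GT–AA, three AT–AG) recodes to canonical GT–AG in full.

## SRE density

Density at an offset is the fraction of junctions with a set hexamer
*starting* there; overlapping occurrences all count (no run-collapsing —
the simpler, information-preserving convention). Windows are 100 nt on the
exonic and intronic side of each splice site, transcript-oriented, each
extended 5 nt so boundary-straddling hexamers are counted; junctions whose
windows would cross a contig end are skipped with the junction count
adjusted. Smoothing is a centred 10-nt moving average. Group comparison:
2×2 Pearson chi-squared (hexamer-start vs non-start positions, group vs
group), 1 df, no continuity correction, small-expected-count warning.
Hexamer lists are user inputs; none are shipped.

## Synthetic data

The generator builds a self-consistent world: splice-site contexts are
sampled from sharp consensus models (dominant base probability 0.95) that
the pipeline then re-estimates as its PWMs, so recovery of every implanted
class is provable rather than probabilistic. U2/U12-like implants deviate
at exactly one terminal dinucleotide and are planted as alternative 5′/3′
variants sharing a site with a canonical junction 30 nt away — the
configuration real non-canonical sites usually occupy — with planted
ψ = 0.30 of a shared depth. Template-switch implants carry a copied 7-nt
repeat and a 0.70-GC intron; homopolymer implants place a 6-nt run inside
a canonical intron with the false junction 7 nt off; edited implants plant
GT–AA/AT–AG termini with A:G pileups of 12:8; SNP-confounded implants get
a VCF record under their donor. Default scale: 100 canonical (8% GC–AG,
12% U12-type AT–AC — enough to train the U12 matrices), 20 U2/U12-like,
10 + 10 artifacts, 5 SNP-confounded, 4 edited, two data sources with 30–60×
junction coverage and 50-nt reads — sizes chosen so a full study simulates
and analyses in seconds while every per-class count is large enough to
expose a systematic mis-assignment.

After assembly every gene is re-checked against its intended label
(dinucleotides, absence of ambiguous canonical placements, planted repeat
and run lengths, DUST clearance) and resampled otherwise, so truth labels
are correct *by construction*. Everything is a pure function of (config,
seed); reads are emitted as gapped alignments (SAM), since alignment
itself is upstream of this package.

What the generator does **not** emulate: sequencing base errors, coverage
overdispersion beyond the planted ranges, intron-length and GC
distributions of real genomes, genuine branch-point/polypyrimidine
variability, or expression-level realism. Passing recovery tests therefore
demonstrates the correctness of the decision logic under its stated
assumptions, not the field error rate of the thresholds on real libraries.

## Numerical and degenerate-input conventions

N in a scored window contributes the column minimum (most pessimistic real
base). A flat matrix column set scores 100 by convention (max = min).
Empty calibration input, zero group coverage, all-N GC regions and
sub-word DUST inputs raise errors rather than returning sentinels. The
acceptance script derives all sub-seeds from one integer and keeps them
below 2³¹.

## Known limitations

- Per-block mismatch counts are not recoverable from plain SAM without
  per-block tags; SAM ingestion conservatively attributes the record's NM
  to every block, which can over-reject EST evidence near the mismatch cap.
- The shared-score combiner (mean of sites, max of models) is one of
  several defensible choices; scores near the 70.00 cutoff can move a few
  points under donor-only or acceptor-only scoring.
- The 1:20 filter's pooled-coverage reading can keep a junction whose
  support is concentrated in a single sample.
- Conservation is exact-coordinate; one-basepair mapping slop in a real
  liftover chain reports NOT_FOUND rather than fuzzy-matching.
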