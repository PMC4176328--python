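# ncsplice

Discovery and vetting of **non-canonical splice sites** from RNA-seq gapped
alignments.

Nearly all human introns carry GT–AG, GC–AG or AT–AC terminal dinucleotides.
The rare junctions with anything else are a mix of genuinely spliced introns
whose surrounding sequence still fits the U2 (major) or U12 (minor)
spliceosome consensus, and technical artifacts: alignment slippage over
SNPs/indels, indel errors next to homopolymers that shift reads off a real
canonical junction, and reverse-transcriptase template switching across
direct repeats. `ncsplice` implements the full vetting pipeline that
separates these cases, plus the downstream analyses a junction catalog
supports.

## What it does

- **Extraction** — junctions from gapped SAM alignments (skipped-region
  gaps), requiring unique mapping and ≥ 8 nt anchors on both sides (≥ 15 nt,
  zero mismatches, for cDNA/EST evidence). Support counts *distinct read
  sequences*; a junction must reach ≥ 3 supporting sequences in ≥ 2
  independent data sources.
- **Filters** — discard non-canonical candidates whose footprint spans
  reported SNPs/indels; DUST triplet-score low-complexity filter;
  user-supplied repeat intervals; diploid maternal/paternal concordance
  (≥ 3 coincident alignments in both haplotypes).
- **Placement ambiguity** — direct repeats at a junction make several intron
  placements excise to the same mature transcript. All equivalent placements
  are enumerated; if any placement is canonical the junction is *rescued* as
  canonical, otherwise the best PWM-fit placement is kept.
- **Classification** — position weight matrices for the U2/U12 donor and
  acceptor sites are trained from the recovered canonical junctions and
  scored on the Shapiro–Senapathy 0–100 scale (junction score = mean of
  donor and acceptor, best of the two spliceosome models). A
  scrambled-sequence null (within-window letter permutation, 95th
  percentile, nearest rank) calibrates the decision threshold. Rule order:
  introns < 80 nt → non-U2/U12; score > 70.00 → U2/U12-like; score between
  the threshold and 70.00 → U2/U12-like only when sharing a splice site
  with a canonical junction; otherwise non-U2/U12.
- **Alternative splicing** — splice-variant groups (shared donor/acceptor,
  transitively closed), event typing (alt 5′/3′, exon skipping/inclusion,
  intron retention), intron usage ψ = junction coverage / group coverage
  with 95% Wilson intervals, and an inclusive 1:20 minor-isoform filter.
- **Artifact signatures** — non-U2/U12 candidates are partitioned into
  near-canonical (both ends ≤ 10 nt from a canonical junction) with/without
  a flanking homopolymer run ≥ 5 nt, template-switch-like (direct repeat
  ≥ 6 nt or %GC ≥ 0.6), and unexplained.
- **RNA editing** — A-to-I editing (read as A>G) at splice-site adenosines
  converts GT–AA and AT–AG termini into canonical GT–AG; pileup evidence is
  scored and edited pairs recoded.
- **SRE density** — exon/intron-identity hexamer (EIE = ESE+ISS,
  IIE = ISE+ESS) positional density in 100-nt windows, 10-nt smoothing, and
  Pearson chi-squared group comparisons.
- **Conservation** — strict same-coordinates + same-dinucleotides test
  through precomputed cross-species interval mappings.
- **Synthetic data** — a first-class generator that builds genomes with
  implanted junctions of every class above, emits SAM/VCF/pileup evidence,
  and guarantees its truth labels by construction.

## Worked example

```sh
ncsplice simulate --seed 3 --outdir sim/
ncsplice classify --genome sim/genome.fa \
    --sam tissueA=sim/tissueA.sam --sam tissueB=sim/tissueB.sam \
    --vcf sim/variants.vcf --pileup sim/pileup.tsv \
    --seed 3 --out classified.tsv
ncsplice track --genome sim/genome.fa --junctions classified.tsv --out junctions.bed
```

The default simulation implants 100 canonical introns, 20 U2/U12-like
non-canonical introns (one deviant terminal dinucleotide each), 10
template-switch artifacts, 10 homopolymer-proximal false junctions, 5
SNP-confounded candidates and 4 edited (GT–AA / AT–AG) junctions. The
classify step prints:

```
threshold 49.70; 24 U2/U12-like, 20 non-U2/U12, 4 edited
```

i.e. the scrambled-null threshold calibrated just below 50 on the 0–100
scale; 24 U2/U12-like junctions (the 20 implants plus the 4 edited sites,
which score like real splice sites before editing is even considered); 20
non-U2/U12 artifacts; and 4 junctions with passing A>G editing evidence,
all of which recode to canonical GT–AG. The 5 SNP-confounded candidates are
discarded by the variant filter and appear in neither class.

The same flow is available as a library:

```python
from ncsplice import SimulationConfig, simulate_reference, simulate_evidence, run_pipeline

cfg = SimulationConfig(seed=3)
genome, truths = simulate_reference(cfg)
records, variants, pileup = simulate_evidence(genome, truths, cfg)
result = run_pipeline(genome, records, variants=variants, pileup=pileup)
```

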