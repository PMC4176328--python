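"""Junction extraction from gapped alignments and the ab initio filters."""

import numpy as np
import pytest

from ncsplice.core import Genome, Junction
from ncsplice.extraction import (
    ExtractionConfig,
    GappedAlignmentRecord,
    build_junction_library,
    diploid_concordance,
    dust_score,
    filter_low_complexity,
    filter_repeat_overlap,
    filter_variant_spanning,
    junctions_from_alignments,
    merge_sources,
    read_sam_records,
)
from ncsplice.simulate import SimulationConfig, simulate_evidence, simulate_reference, write_sam


def _spanning_record(read_id, seq, chrom, start, end, left, right, unique=True):
    return GappedAlignmentRecord(
        read_id=read_id,
        read_sequence=seq,
        chrom=chrom,
        strand="+",
        blocks=[((start - left, start), (0, left)),
                ((end, end + right), (left, left + right))],
        unique=unique,
    )


class TestJunctionsFromAlignments:
    def test_support_counts_distinct_sequences_not_alignments(self):
        recs = [
            _spanning_record(f"r{i}", "ACGTACGTACGT", "c", 100, 200, 10, 12)
            for i in range(3)
        ]
        out = junctions_from_alignments(recs, ExtractionConfig(), "src")
        assert out[("c", 100, 200, "+")].support == {"src": 1}

    def test_short_anchor_contributes_nothing(self):
        rec = _spanning_record("r", "A" * 37, "c", 100, 200, 7, 30)
        out = junctions_from_alignments([rec], ExtractionConfig(), "src")
        assert out == {}

    def test_anchor_boundary_is_inclusive(self):
        rec = _spanning_record("r", "A" * 16, "c", 100, 200, 8, 8)
        out = junctions_from_alignments([rec], ExtractionConfig(), "src")
        assert ("c", 100, 200, "+") in out

    def test_multimappers_excluded(self):
        rec = _spanning_record("r", "A" * 20, "c", 100, 200, 10, 10, unique=False)
        assert junctions_from_alignments([rec], ExtractionConfig(), "src") == {}

    def test_est_mode_requires_long_clean_anchors(self):
        rec = _spanning_record("r", "A" * 30, "c", 100, 200, 15, 15)
        rec.mismatches = [1, 0]
        cfg = ExtractionConfig()
        assert junctions_from_alignments([rec], cfg, "est", est_mode=True) == {}
        rec.mismatches = [0, 0]
        assert ("c", 100, 200, "+") in junctions_from_alignments(
            [rec], cfg, "est", est_mode=True
        )

    def test_simulator_truth_support_recovered_exactly(self, sim_world):
        cfg, genome, truths, records, _, _ = sim_world
        sample = cfg.samples[0]
        out = junctions_from_alignments(
            records[sample], ExtractionConfig(), sample
        )
        for t in truths:
            if t.support.get(sample, 0) == 0:
                continue
            assert out[t.key].support[sample] == t.support[sample]


class TestMergeSources:
    def _jset(self, label, n):
        return {("c", 10, 90, "+"): Junction("c", 10, 90, "+", support={label: n})}

    def test_present_in_two_sources_retained(self):
        cfg = ExtractionConfig()
        merged = merge_sources([self._jset("A", 3), self._jset("B", 4)], cfg)
        assert merged[("c", 10, 90, "+")].support == {"A": 3, "B": 4}

    def test_single_source_dropped(self):
        assert merge_sources([self._jset("A", 5)], ExtractionConfig()) == {}

    def test_pooling_is_not_presence(self):
        merged = merge_sources(
            [self._jset("A", 2), self._jset("B", 2)], ExtractionConfig()
        )
        assert merged == {}

    def test_duplicate_source_labels_rejected(self):
        with pytest.raises(ValueError):
            merge_sources([self._jset("A", 3), self._jset("A", 3)], ExtractionConfig())

    def test_idempotent(self):
        cfg = ExtractionConfig()
        merged = merge_sources([self._jset("A", 3), self._jset("B", 4)], cfg)
        again = merge_sources([merged], cfg)
        assert {k: j.support for k, j in again.items()} == {
            k: j.support for k, j in merged.items()
        }


def _genome_with_candidate():
    # GA-AG candidate intron at [50, 150) and GT-AG canonical at [250, 350)
    rng = np.random.default_rng(3)
    seq = list("".join(rng.choice(list("ACGT"), size=400)))
    seq[50:52], seq[148:150] = "GA", "AG"
    seq[250:252], seq[348:350] = "GT", "AG"
    g = Genome({"c": "".join(seq)})
    return g, Junction("c", 50, 150, "+"), Junction("c", 250, 350, "+")


class TestVariantFilter:
    def test_snp_at_donor_discards_candidate(self):
        g, cand, canon = _genome_with_candidate()
        kept, disc = filter_variant_spanning([cand], [("c", 51, 52)], g)
        assert kept == [] and disc[0][1] == "variant_spanning"

    def test_deep_intronic_snp_kept(self):
        g, cand, _ = _genome_with_candidate()
        kept, disc = filter_variant_spanning([cand], [("c", 100, 101)], g)
        assert kept == [cand] and disc == []

    def test_canonical_junction_passes_untouched(self):
        g, _, canon = _genome_with_candidate()
        kept, disc = filter_variant_spanning([canon], [("c", 251, 252)], g)
        assert kept == [canon] and disc == []

    def test_anchor_window_overlap_discards(self):
        g, cand, _ = _genome_with_candidate()
        kept, disc = filter_variant_spanning([cand], [("c", 30, 31)], g, anchor_span=25)
        assert kept == []


class TestDust:
    @staticmethod
    def brute_force(seq, window=64, word=3):
        best = 0.0
        w = min(window, len(seq))
        for ws in range(len(seq) - w + 1):
            sub = seq[ws : ws + w]
            triplets = [sub[i : i + 3] for i in range(len(sub) - 2)]
            counts = {}
            for t in triplets:
                counts[t] = counts.get(t, 0) + 1
            if len(triplets) > 1:
                s = sum(c * (c - 1) / 2 for c in counts.values()) / (len(triplets) - 1)
                best = max(best, s)
        return best

    def test_homopolymer_is_extreme(self):
        assert dust_score("A" * 64) > 2.0

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=64))
            assert dust_score(seq) == pytest.approx(self.brute_force(seq), abs=1e-12)

    def test_matches_brute_force_on_periodic_sequence(self):
        seq = "ACGT" * 16
        assert dust_score(seq) == pytest.approx(self.brute_force(seq), abs=1e-12)

    def test_too_short_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            dust_score("AC")

    def test_filter_flags_homopolymer_anchor(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=100)) + "A" * 64
        seq = seq + "".join(rng.choice(list("ACGT"), size=200))
        g = Genome({"c": seq})
        j = Junction("c", 164, 300, "+")  # 5' exonic anchor is the A-run
        kept, disc = filter_low_complexity([j], g, ExtractionConfig())
        assert disc and disc[0][1] == "low_complexity"


class TestFilterCommutation:
    def test_variant_and_dust_filters_commute(self):
        g, cand, canon = _genome_with_candidate()
        variants = [("c", 51, 52)]
        cfg = ExtractionConfig()
        jn = [cand, canon]
        a, _ = filter_variant_spanning(jn, variants, g)
        a, _ = filter_low_complexity(a, g, cfg)
        b, _ = filter_low_complexity(jn, g, cfg)
        b, _ = filter_variant_spanning(b, variants, g)
        assert {j.key for j in a} == {j.key for j in b}


class TestDiploidConcordance:
    def _maps(self):
        return {
            ("maternal", "mat1", 100, 200, "+"): ("c", 100, 200, "+"),
            ("paternal", "pat1", 105, 205, "+"): ("c", 100, 200, "+"),
        }

    def test_coincident_with_enough_support_kept(self):
        mat = {("mat1", 100, 200, "+"): Junction("mat1", 100, 200, "+", support={"m": 3})}
        pat = {("pat1", 105, 205, "+"): Junction("pat1", 105, 205, "+", support={"p": 5})}
        kept, excluded = diploid_concordance(mat, pat, self._maps())
        assert len(kept) == 1 and kept[0].key == ("c", 100, 200, "+")

    def test_one_haplotype_below_three_dropped(self):
        mat = {("mat1", 100, 200, "+"): Junction("mat1", 100, 200, "+", support={"m": 3})}
        pat = {("pat1", 105, 205, "+"): Junction("pat1", 105, 205, "+", support={"p": 2})}
        kept, _ = diploid_concordance(mat, pat, self._maps())
        assert kept == []

    def test_unmapped_junction_excluded_with_reason(self):
        mat = {("mat1", 900, 990, "+"): Junction("mat1", 900, 990, "+", support={"m": 9})}
        kept, excluded = diploid_concordance(mat, {}, self._maps())
        assert kept == [] and excluded[0][1] == "unmapped"


class TestJunctionLibrary:
    def test_flank_concatenation(self, toy_genome):
        recs = build_junction_library(toy_genome, [Junction("chr1", 3, 11, "+")], 3)
        assert len(recs) == 1 and recs[0][1] == "AAAAAA"

    def test_record_length_is_twice_flank(self, sim_world):
        _, genome, truths, _, _, _ = sim_world
        recs = build_junction_library(genome, [truths[0].junction], 42)
        assert len(recs[0][1]) == 84

    def test_regeneration_oracle(self, sim_world):
        """Rebuilding every record from raw genome slices reproduces the
        library byte-identically."""
        _, genome, truths, _, _, _ = sim_world
        jn = [t.junction for t in truths[:20]]
        recs = build_junction_library(genome, jn, 30)
        assert len(recs) == 20
        for (name, seq), j in zip(recs, jn):
            s = genome.sequences[j.chrom]
            assert seq == s[j.start - 30 : j.start] + s[j.end : j.end + 30]

    def test_edge_junction_skipped(self):
        g = Genome({"c": "A" * 30})
        recs = build_junction_library(g, [Junction("c", 5, 25, "+")], 10)
        assert recs == []


class TestRepeatFilter:
    def test_anchor_overlap_discards(self):
        g, cand, _ = _genome_with_candidate()
        kept, disc = filter_repeat_overlap([cand], [("c", 40, 60)])
        assert kept == [] and disc[0][1] == "repeat_overlap"
        kept, disc = filter_repeat_overlap([cand], [("c", 0, 10)])
        assert kept == [cand]


class TestSamRoundTrip:
    def test_written_sam_reproduces_junction_set(self, tmp_path, sim_world):
        cfg, genome, truths, records, _, _ = sim_world
        sample = cfg.samples[0]
        path = tmp_path / "reads.sam"
        write_sam(path, genome, records[sample])
        parsed = list(read_sam_records(path))
        direct = junctions_from_alignments(records[sample], ExtractionConfig(), sample)
        via_sam = junctions_from_alignments(parsed, ExtractionConfig(), sample)
        assert {k: j.support for k, j in via_sam.items()} == {
            k: j.support for k, j in direct.items()
        }
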