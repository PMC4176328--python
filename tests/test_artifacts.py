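"""Artifact signatures: near-canonical distances, homopolymer runs, %GC."""

import numpy as np
import pytest

from ncsplice.artifacts import (
    ArtifactConfig,
    Partition,
    gc_fraction,
    homopolymer_run,
    near_canonical_partition,
    partition_candidates,
)
from ncsplice.core import Genome, Junction


class TestNearCanonical:
    def _canon(self):
        return [Junction("c", 100, 200, "+")]

    def test_both_ends_within_bound(self):
        flag, dd, da = near_canonical_partition(
            Junction("c", 103, 203, "+"), self._canon()
        )
        assert flag and dd == 3 and da == 3

    def test_one_far_end_fails(self):
        flag, dd, da = near_canonical_partition(
            Junction("c", 103, 211, "+"), self._canon()
        )
        assert not flag and da == 11

    def test_boundary_ten_vs_eleven(self):
        assert near_canonical_partition(Junction("c", 110, 210, "+"), self._canon())[0]
        assert not near_canonical_partition(Junction("c", 111, 211, "+"), self._canon())[0]

    def test_strand_must_match(self):
        flag, dd, da = near_canonical_partition(
            Junction("c", 103, 203, "-"), self._canon()
        )
        assert not flag and dd is None

    def test_matches_all_pairs_scan(self):
        """500 random configurations against a brute-force all-pairs scan."""
        rng = np.random.default_rng(4)
        for _ in range(500):
            canon = [
                Junction("c", int(s), int(s) + int(rng.integers(50, 200)), "+")
                for s in rng.integers(0, 5000, size=5)
            ]
            cs = int(rng.integers(0, 5000))
            cand = Junction("c", cs, cs + int(rng.integers(50, 200)), "+")
            flag, _, _ = near_canonical_partition(cand, canon)
            brute = any(
                abs(c.donor_pos - cand.donor_pos) <= 10
                and abs(c.acceptor_pos - cand.acceptor_pos) <= 10
                for c in canon
            )
            assert flag == brute


class TestHomopolymerRun:
    def _genome(self, left_flank, right_flank):
        middle = "GACGTTACGGAT" * 10
        seq = "ACGTACGTAC" + left_flank + middle + right_flank + "ACGTACGTAC"
        start = 10 + len(left_flank)
        end = start + len(middle)
        return Genome({"c": seq}), Junction("c", start, end, "+")

    def test_five_base_run_flagged(self):
        g, j = self._genome("GTTTTT", "ACACAC")  # run of 5 T adjacent to donor
        run, flagged = homopolymer_run(g, j)
        assert run == 5 and flagged

    def test_four_base_run_not_flagged(self):
        g, j = self._genome("GCTTTT", "ACACAC")
        run, flagged = homopolymer_run(g, j)
        assert run == 4 and not flagged

    def test_acceptor_side_run_counts(self):
        g, j = self._genome("ACACAG", "AAAAAAAT")
        run, flagged = homopolymer_run(g, j)
        assert run == 7 and flagged

    def test_matches_run_length_scanner(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            seq = "".join(rng.choice(list("ACGT"), size=120, p=[0.4, 0.1, 0.1, 0.4]))
            start = int(rng.integers(20, 50))
            end = int(rng.integers(start + 10, 100))
            g = Genome({"c": seq})
            run, _ = homopolymer_run(g, Junction("c", start, end, "+"))

            def scan_left(pos):
                n = 0
                while pos - 1 - n >= 0 and seq[pos - 1 - n] == seq[pos - 1]:
                    n += 1
                return n

            def scan_right(pos):
                n = 0
                while pos + n < len(seq) and seq[pos + n] == seq[pos]:
                    n += 1
                return n

            assert run == max(scan_left(start), scan_right(end))


class TestGcFraction:
    @pytest.mark.parametrize(
        "intron,expected", [("GCGCGC", 1.0), ("ATATAT", 0.0), ("GCAT", 0.5)]
    )
    def test_simple_fractions(self, intron, expected):
        g = Genome({"c": "AAAA" + intron + "TTTT"})
        j = Junction("c", 4, 4 + len(intron), "+")
        assert gc_fraction(g, j) == pytest.approx(expected)

    def test_n_excluded_from_denominator(self):
        g = Genome({"c": "AAAA" + "GCNN" + "TTTT"})
        assert gc_fraction(g, Junction("c", 4, 8, "+")) == pytest.approx(1.0)

    def test_all_n_region_is_an_error(self):
        g = Genome({"c": "AAAA" + "NNNN" + "TTTT"})
        with pytest.raises(ValueError):
            gc_fraction(g, Junction("c", 4, 8, "+"))


class TestPartition:
    def test_partition_examples(self):
        # canonical intron at [100, 200); a false junction 7 nt inside it
        # with a 5-nt homopolymer in its (from its viewpoint exonic) left
        # flank; an isolated GC-rich candidate with an 8-nt direct repeat;
        # and an isolated AT-rich candidate matching no signature
        rng = np.random.default_rng(9)
        seq = list(
            "".join(rng.choice(list("ACGT"), size=600, p=[0.45, 0.05, 0.05, 0.45]))
        )
        seq[100:102], seq[198:200] = "GT", "AG"
        seq[102:107] = "TTTTT"
        canon = Junction("c", 100, 200, "+")
        near = Junction("c", 107, 207, "+")
        seq[400:500] = list("GC" * 50)
        seq[400:408] = list("GCCGGCCG")
        seq[500:508] = list("GCCGGCCG")  # direct repeat across [400, 500)
        iso_ts = Junction("c", 400, 500, "+")
        iso_plain = Junction("c", 250, 330, "+")
        g = Genome({"c": "".join(seq)})
        reports = {
            r.junction_key: r
            for r in partition_candidates([near, iso_ts, iso_plain], [canon], g)
        }
        assert reports[near.key].partition == Partition.NEAR_CANONICAL_HOMOPOLYMER
        assert reports[near.key].homopolymer_run >= 5
        assert reports[iso_ts.key].partition == Partition.TEMPLATE_SWITCH_LIKE
        assert reports[iso_ts.key].direct_repeat_length >= 8
        assert reports[iso_plain.key].partition == Partition.UNEXPLAINED

    def test_partition_is_exhaustive_and_exclusive(self, sim_result):
        _, genome, _, result = sim_result
        reports = result.artifact_reports
        assert len(reports) == len({r.junction_key for r in reports})
        valid = {
            Partition.NEAR_CANONICAL_HOMOPOLYMER,
            Partition.NEAR_CANONICAL_OTHER,
            Partition.TEMPLATE_SWITCH_LIKE,
            Partition.UNEXPLAINED,
        }
        assert all(r.partition in valid for r in reports)

    def test_partition_rederivable_from_reported_measurements(self, sim_result):
        cfg_a = ArtifactConfig()
        _, genome, _, result = sim_result
        for r in result.artifact_reports:
            near = (
                r.donor_distance is not None
                and r.donor_distance <= cfg_a.max_dist
                and r.acceptor_distance <= cfg_a.max_dist
            )
            if near and r.homopolymer_run >= cfg_a.min_run:
                expected = Partition.NEAR_CANONICAL_HOMOPOLYMER
            elif near:
                expected = Partition.NEAR_CANONICAL_OTHER
            elif (
                r.direct_repeat_length >= cfg_a.repeat_min
                or r.gc_fraction >= cfg_a.gc_min
            ):
                expected = Partition.TEMPLATE_SWITCH_LIKE
            else:
                expected = Partition.UNEXPLAINED
            assert r.partition == expected
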