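import numpy as np
import pytest

from readaudit.coverage import (
    accumulate_depth,
    bin_distributions,
    cigar_reference_intervals,
    covered_scaffold_pct,
    exact_match_align,
    mapped_over_cleaned_pct,
    run2ref,
    summarize_coverage,
)
from readaudit.errors import ConsistencyError, ReadAuditError
from readaudit.io_formats import AlignmentRecord, ReferenceScaffold, SequenceRead

from conftest import as_reads, random_sequence
from oracles import depth_oracle


def rec(flag, rname, pos, cigar):
    return AlignmentRecord(flag=flag, rname=rname, pos=pos, cigar=cigar)


class TestCigarReferenceIntervals:
    def test_simple_match(self):
        intervals, span = cigar_reference_intervals(11, "5M")
        assert intervals == [(10, 15)] and span == 5

    def test_deletion_advances_without_cover(self):
        intervals, span = cigar_reference_intervals(1, "3M2D3M")
        assert intervals == [(0, 3), (5, 8)] and span == 8

    def test_insertion_consumes_no_reference(self):
        intervals, span = cigar_reference_intervals(1, "3M2I3M")
        assert intervals == [(0, 6)] and span == 6

    def test_skip_and_clips(self):
        intervals, span = cigar_reference_intervals(5, "2S3M10N2M3H")
        assert intervals == [(4, 7), (17, 19)] and span == 15

    def test_eq_and_x_cover(self):
        intervals, _ = cigar_reference_intervals(1, "2=1X2=")
        assert intervals == [(0, 5)]


class TestAccumulateDepth:
    SCAFFOLDS = [ReferenceScaffold("s1", 10)]

    def test_hand_accumulation(self):
        depths, n = accumulate_depth(
            [rec(0, "s1", 1, "5M"), rec(0, "s1", 3, "5M")], self.SCAFFOLDS
        )
        assert depths["s1"].tolist() == [1, 1, 2, 2, 2, 1, 1, 0, 0, 0]
        assert n == 2

    def test_unmapped_only(self):
        depths, n = accumulate_depth([rec(4, "*", 0, "*")], self.SCAFFOLDS)
        assert depths["s1"].sum() == 0 and n == 0

    @pytest.mark.parametrize("flag", [0x100, 0x800])
    def test_secondary_and_supplementary_excluded(self, flag):
        depths, n = accumulate_depth([rec(flag, "s1", 1, "5M")], self.SCAFFOLDS)
        assert depths["s1"].sum() == 0 and n == 0

    def test_out_of_bounds_is_error(self):
        with pytest.raises(ConsistencyError):
            accumulate_depth([rec(0, "s1", 8, "5M")], self.SCAFFOLDS)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scaffolds = [
            ReferenceScaffold(f"s{i}", int(rng.integers(20, 100)))
            for i in range(int(rng.integers(1, 4)))
        ]
        records = _random_alignments(rng, scaffolds, int(rng.integers(0, 30)))
        depths, n = accumulate_depth(records, scaffolds)
        exp_depths, exp_n = depth_oracle(
            records, {s.name: s.length for s in scaffolds}
        )
        assert n == exp_n
        for s in scaffolds:
            assert depths[s.name].tolist() == exp_depths[s.name]

    def test_depth_sum_equals_covered_op_spans(self):
        rng = np.random.default_rng(3)
        scaffolds = [ReferenceScaffold("s1", 200)]
        records = _random_alignments(rng, scaffolds, 25)
        depths, _ = accumulate_depth(records, scaffolds)
        expected = 0
        for r in records:
            if r.flag & 0x904 or not r.usable:
                continue
            intervals, _ = cigar_reference_intervals(r.pos, r.cigar)
            expected += sum(e - s for s, e in intervals)
        assert int(depths["s1"].sum()) == expected


def _random_alignments(rng, scaffolds, n):
    """Random records with M/I/D/S ops, some unmapped/secondary."""
    records = []
    for _ in range(n):
        roll = rng.random()
        if roll < 0.15:
            records.append(rec(4, "*", 0, "*"))
            continue
        scaffold = scaffolds[int(rng.integers(0, len(scaffolds)))]
        parts = []
        span = 0
        for _ in range(int(rng.integers(1, 4))):
            op = str(rng.choice(["M", "I", "D", "S", "M"]))
            length = int(rng.integers(1, 8))
            parts.append(f"{length}{op}")
            if op in "MD":
                span += length
        span = max(span, 1)
        if span >= scaffold.length:
            continue
        pos = int(rng.integers(1, scaffold.length - span + 1))
        flag = 0x100 if roll > 0.9 else 0
        records.append(rec(flag, scaffold.name, pos, "".join(parts)))
    return records


class TestSummarizeCoverage:
    def test_ratio_rows_match_published_scale(self):
        assert round(covered_scaffold_pct(3_960, 5_191), 2) == 76.29
        assert round(mapped_over_cleaned_pct(6_573_572, 7_524_261), 2) == 87.37

    def test_equal_breadths_give_zero_evenness(self):
        scaffolds = [ReferenceScaffold("a", 4), ReferenceScaffold("b", 4)]
        depths = {"a": np.array([1, 1, 0, 0]), "b": np.array([2, 3, 0, 0])}
        summary, _ = summarize_coverage(depths, scaffolds, 2, 2)
        assert summary.evenness == 0.0

    def test_half_covered_two_scaffold_genome(self):
        # one read covering one whole scaffold out of two equal-length scaffolds:
        # genome breadth 50%, evenness = sd/mean of {100, 0} = 50/50 = 1.0
        scaffolds = [ReferenceScaffold("a", 5), ReferenceScaffold("b", 5)]
        depths = {"a": np.ones(5, dtype=int), "b": np.zeros(5, dtype=int)}
        summary, per_scaffold = summarize_coverage(depths, scaffolds, 1, 2)
        assert summary.genome_breadth_pct == 50.0
        assert summary.evenness == 1.0
        assert summary.n_scaffolds_covered == 1
        assert summary.covered_scaffold_pct == 50.0

    def test_genome_breadth_is_length_weighted(self):
        rng = np.random.default_rng(11)
        scaffolds = [
            ReferenceScaffold(f"s{i}", int(rng.integers(5, 50))) for i in range(6)
        ]
        depths = {
            s.name: (rng.random(s.length) < 0.4).astype(int) for s in scaffolds
        }
        summary, per_scaffold = summarize_coverage(depths, scaffolds, 0, 1)
        total_cov = sum(s.covered_bases for s in per_scaffold)
        total_len = sum(s.length for s in per_scaffold)
        assert summary.genome_breadth_pct == pytest.approx(100 * total_cov / total_len)

    def test_evenness_scale_invariant(self):
        # doubling every scaffold's covered bases and length leaves breadths,
        # hence evenness, unchanged
        scaffolds1 = [ReferenceScaffold("a", 4), ReferenceScaffold("b", 8)]
        depths1 = {"a": np.array([1, 1, 0, 0]), "b": np.array([1, 0, 0, 0, 0, 0, 0, 0])}
        scaffolds2 = [ReferenceScaffold("a", 8), ReferenceScaffold("b", 16)]
        depths2 = {
            "a": np.array([1, 1, 1, 1, 0, 0, 0, 0]),
            "b": np.array([1, 1] + [0] * 14),
        }
        s1, _ = summarize_coverage(depths1, scaffolds1, 0, 1)
        s2, _ = summarize_coverage(depths2, scaffolds2, 0, 1)
        assert s1.evenness == pytest.approx(s2.evenness)

    def test_empty_genome_is_error(self):
        with pytest.raises(ReadAuditError):
            summarize_coverage({}, [], 0, 0)


class TestBinDistributions:
    def cov(self, length, covered, mapped):
        from readaudit.coverage import ScaffoldCoverage

        return ScaffoldCoverage("s", length, covered, mapped)

    def test_breadth_bin_closed_at_upper_edge(self):
        # breadth exactly 40% falls in (30,40]
        breadth_hist, _ = bin_distributions([self.cov(10, 4, 4)])
        assert dict(breadth_hist)["(30,40]"] == 1

    def test_zero_coverage_scaffold_in_zero_bins(self):
        breadth_hist, depth_hist = bin_distributions([self.cov(10, 0, 0)])
        assert dict(breadth_hist)["0"] == 1 and dict(depth_hist)["0"] == 1

    def test_depth_bins(self):
        breadth_hist, depth_hist = bin_distributions(
            [
                self.cov(10, 10, 10),   # depth exactly 1 -> (0,1]
                self.cov(10, 10, 15),   # 1.5 -> (1,2]
                self.cov(10, 10, 40),   # 4 -> (2,4]
                self.cov(10, 10, 90),   # 9 -> (4,10]
                self.cov(10, 10, 101),  # 10.1 -> (10,inf)
            ]
        )
        d = dict(depth_hist)
        assert d["(0,1]"] == d["(1,2]"] == d["(2,4]"] == d["(4,10]"] == d["(10,inf)"] == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(5)
        covs = [
            self.cov(100, int(rng.integers(0, 101)), int(rng.integers(0, 500)))
            for _ in range(137)
        ]
        covs = [c for c in covs if (c.covered_bases == 0) == (c.mapped_bases == 0)]
        breadth_hist, depth_hist = bin_distributions(covs)
        assert sum(c for _, c in breadth_hist) == len(covs)
        assert sum(c for _, c in depth_hist) == len(covs)

    def test_full_breadth_in_top_bin(self):
        breadth_hist, _ = bin_distributions([self.cov(7, 7, 7)])
        assert dict(breadth_hist)["(90,100]"] == 1


class TestExactMatchAlign:
    SCAFFOLDS = [
        ReferenceScaffold("s1", 12, sequence="ACGTACGTAAAA"),
        ReferenceScaffold("s2", 8, sequence="TTTTCCCC"),
    ]

    def test_prefix_maps_at_position_one(self):
        (record,) = exact_match_align(as_reads(["ACGTACG"]), self.SCAFFOLDS[:1])
        assert (record.flag, record.rname, record.pos, record.cigar) == (0, "s1", 1, "7M")

    def test_absent_read_unmapped(self):
        (record,) = exact_match_align(as_reads(["GGGGG"]), self.SCAFFOLDS)
        assert record.flag & 0x4 and not record.usable

    def test_multi_hit_primary_then_secondary(self):
        records = exact_match_align(as_reads(["ACGT"]), self.SCAFFOLDS)
        assert [(r.flag, r.pos) for r in records] == [(0, 1), (0x100, 5)]

    def test_cross_scaffold_search(self):
        (record,) = exact_match_align(as_reads(["TTTTC"]), self.SCAFFOLDS)
        assert record.rname == "s2" and record.pos == 1


class TestRun2Ref:
    def test_synthetic_truth(self, paper_fixture):
        scaffolds, reads, truth = paper_fixture
        result = run2ref(scaffolds, reads=reads)
        assert result.summary.n_scaffolds_covered == 10
        assert result.summary.n_scaffolds_total == 10
        for s in result.per_scaffold:
            expected = sum(e - b for b, e in truth.expected_covered[s.name])
            assert s.covered_bases == expected
        genome_expected = sum(
            e - b for ivs in truth.expected_covered.values() for b, e in ivs
        )
        assert result.summary.genome_breadth_pct == pytest.approx(
            100 * genome_expected / 1500
        )

    def test_covered_positions_equal_truth_windows(self, paper_fixture):
        scaffolds, reads, truth = paper_fixture
        result = run2ref(scaffolds, reads=reads)
        for s in scaffolds:
            covered = np.zeros(s.length, dtype=bool)
            for b, e in truth.expected_covered[s.name]:
                covered[b:e] = True
            assert ((result.depths[s.name] > 0) == covered).all()

    def test_empty_sam(self, tmp_path):
        p = tmp_path / "empty.sam"
        p.write_text("@SQ\tSN:s1\tLN:10\n@SQ\tSN:s2\tLN:10\n")
        result = run2ref([], sam_path=p)
        assert result.summary.genome_breadth_pct == 0.0
        assert result.summary.genome_depth == 0.0
        assert result.summary.n_scaffolds_covered == 0

    def test_sam_and_reads_mutually_exclusive(self):
        with pytest.raises(ReadAuditError):
            run2ref([], reads=[], sam_path="x.sam")

    def test_sam_header_length_mismatch_detected(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text("@SQ\tSN:s1\tLN:99\n")
        with pytest.raises(ConsistencyError):
            run2ref([ReferenceScaffold("s1", 100, sequence="A" * 100)], sam_path=p)

    def test_sam_route_equals_internal_aligner_route(self, tmp_path, paper_fixture):
        """Writing the internal aligner's records as SAM and re-ingesting them
        reproduces the coverage summary exactly."""
        scaffolds, reads, _ = paper_fixture
        records = exact_match_align(reads, scaffolds)
        p = tmp_path / "x.sam"
        with open(p, "w") as fh:
            for s in scaffolds:
                fh.write(f"@SQ\tSN:{s.name}\tLN:{s.length}\n")
            for i, r in enumerate(records):
                fh.write(
                    f"q{i}\t{r.flag}\t{r.rname}\t{r.pos}\t60\t{r.cigar}\t*\t0\t0\t*\t*\n"
                )
        via_reads = run2ref(scaffolds, reads=reads)
        via_sam = run2ref(scaffolds, sam_path=p)
        assert via_sam.summary == via_reads.summary
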