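"""Segment/probe conversion: approximation semantics, the four QC
criteria, status partition, and file-level behaviour."""

import pytest

from seglift import (
    ApproxParams,
    ConversionStatus,
    Probe,
    QCParams,
    Reason,
    Segment,
    approximate_position,
    build_index,
    convert_probe,
    convert_probe_file,
    convert_segment,
    convert_segment_file,
    parse_chain_text,
)

from conftest import IDENTITY_CHAIN, MINUS_CHAIN, TWO_BLOCK_CHAIN

DIRECT = ConversionStatus.DIRECT
APPROX = ConversionStatus.APPROX
REJECTED = ConversionStatus.REJECTED
UNCONV = ConversionStatus.UNCONVERTIBLE


class TestApproximatePosition:
    def test_directly_liftable_returns_shift_zero(self, two_block_index):
        mp, shift = approximate_position(two_block_index, "chr1", 50, ApproxParams(50, 10))
        assert (mp.pos, shift) == (150, 0)

    def test_nearest_candidate_wins_lower_coordinate_on_tie(self, two_block_index):
        # gap is source [100,150): from 120, candidates 110/130, 100/140 are
        # all in the gap; 90 and 150 are both liftable at distance 30 and the
        # lower source coordinate wins -> source 90 -> dest 190, shift -30
        mp, shift = approximate_position(two_block_index, "chr1", 120, ApproxParams(50, 10))
        assert (mp.pos, shift) == (190, -30)

    def test_unreachable_within_range_returns_none(self, two_block_index):
        assert approximate_position(two_block_index, "chr1", 120, ApproxParams(20, 10)) is None

    def test_range_zero_disables_search(self, two_block_index):
        assert approximate_position(two_block_index, "chr1", 120, ApproxParams(0, 10)) is None

    def test_candidates_below_zero_skipped(self, two_block_index):
        # from source 2 every on-grid candidate <= range is liftable anyway
        mp, shift = approximate_position(two_block_index, "chr1", 2, ApproxParams(50, 10))
        assert shift == 0

    @pytest.mark.parametrize("bad", [dict(range=-1), dict(step_size=0)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ApproxParams(**{"range": 100, "step_size": 10, **bad})


class TestConvertSegment:
    def test_identity_segment_unchanged(self, identity_index):
        res = convert_segment(Segment("s", "chr1", 101, 200), identity_index)
        assert res.status is DIRECT
        assert (res.new_chrom, res.new_start, res.new_end) == ("chr1", 101, 200)
        assert res.length_ratio == 1.0
        assert res.approx_shift_start == res.approx_shift_end == 0

    def test_length_ratio_rejection(self):
        # dest interval stretches to 250 bp: ratio 100/250 = 0.4 <= 1/2
        chain = "chain 80 chr1 1000 + 0 100 chrB 1000 + 0 250 3\n50\t0\t150\n50\n"
        index = build_index(parse_chain_text(chain))
        res = convert_segment(Segment("s", "chr1", 1, 100), index, QCParams(2.0))
        assert res.status is REJECTED
        assert res.reason is Reason.LENGTH_RATIO_OUT_OF_BOUNDS
        assert res.length_ratio == pytest.approx(0.4)
        assert res.new_start is None  # no coordinates for rejected rows

    @pytest.mark.parametrize(
        "chain, seg_end, expect_rejected",
        [
            # old 100 -> new 50: ratio exactly 2.0, strict bound -> rejected
            ("chain 10 chr1 200 + 0 100 chrX 50 + 0 50 9\n25\t50\t0\n25\n", 100, True),
            # old 50 -> new 100: ratio exactly 0.5 -> rejected
            ("chain 10 chr1 200 + 0 50 chrX 100 + 0 100 8\n25\t0\t50\n25\n", 50, True),
            # old 100 -> new 51: ratio ~1.96 < 2 -> kept
            ("chain 10 chr1 200 + 0 100 chrX 51 + 0 51 7\n26\t49\t0\n25\n", 100, False),
        ],
    )
    def test_beta_boundary_is_strict(self, chain, seg_end, expect_rejected):
        index = build_index(parse_chain_text(chain))
        res = convert_segment(Segment("s", "chr1", 1, seg_end), index, QCParams(2.0))
        if expect_rejected:
            assert res.status is REJECTED and res.reason is Reason.LENGTH_RATIO_OUT_OF_BOUNDS
        else:
            assert res.status is DIRECT

    def test_chromosome_mismatch(self):
        chains = (
            "chain 50 chr1 400 + 0 100 chrA 400 + 0 100 1\n100\n\n"
            "chain 50 chr1 400 + 100 200 chrB 400 + 100 200 2\n100\n"
        )
        index = build_index(parse_chain_text(chains))
        res = convert_segment(Segment("s", "chr1", 1, 200), index)
        assert (res.status, res.reason) == (REJECTED, Reason.CHROMOSOME_MISMATCH)

    def test_strand_mismatch(self):
        chains = (
            "chain 50 chr1 400 + 0 100 chrA 400 + 0 100 1\n100\n\n"
            "chain 50 chr1 400 + 100 200 chrA 400 - 100 200 2\n100\n"
        )
        index = build_index(parse_chain_text(chains))
        res = convert_segment(Segment("s", "chr1", 1, 200), index)
        assert (res.status, res.reason) == (REJECTED, Reason.STRAND_MISMATCH)

    def test_inverted_order_swapped_and_kept(self, minus_index):
        res = convert_segment(Segment("s", "chr2", 11, 20), minus_index)
        assert res.status is DIRECT
        assert res.orientation_flipped
        assert (res.new_start, res.new_end) == (981, 990)
        assert res.length_ratio == 1.0

    def test_endpoint_rescued_by_approximation(self, two_block_index):
        # segment end falls in the source gap [100,150); rescue within 50 bp
        seg = Segment("s", "chr1", 1, 121)
        res = convert_segment(seg, two_block_index, approx=ApproxParams(50, 10))
        assert res.status is APPROX
        assert res.approx_shift_start == 0 and res.approx_shift_end == -30
        assert (res.new_start, res.new_end) == (101, 191)

    def test_unconvertible_when_rescue_out_of_range(self, two_block_index):
        res = convert_segment(
            Segment("s", "chr1", 1, 121), two_block_index, approx=ApproxParams(20, 10)
        )
        assert (res.status, res.reason) == (UNCONV, Reason.END_UNMAPPED)

    def test_start_unmapped_reported_first(self, two_block_index):
        res = convert_segment(
            Segment("s", "chr1", 120, 130), two_block_index, approx=ApproxParams(0, 10)
        )
        assert (res.status, res.reason) == (UNCONV, Reason.START_UNMAPPED)

    def test_monotone_in_beta(self, two_block_index):
        # stretching chain again: larger beta can only keep more segments
        chain = "chain 80 chr1 1000 + 0 100 chrB 1000 + 0 250 3\n50\t0\t150\n50\n"
        index = build_index(parse_chain_text(chain))
        seg = Segment("s", "chr1", 1, 100)
        kept = [convert_segment(seg, index, QCParams(beta)).converted for beta in (1.5, 2.0, 2.6, 10.0)]
        assert kept == sorted(kept)  # once kept, stays kept
        assert convert_segment(seg, index, QCParams(1e9)).converted


class TestConvertProbe:
    def test_direct(self, identity_index):
        res = convert_probe(Probe("p", "chr1", 500), identity_index)
        assert (res.status, res.new_chrom, res.new_pos) == (DIRECT, "chr1", 500)

    def test_approximated_with_recorded_shift(self, two_block_index):
        res = convert_probe(Probe("p", "chr1", 121), two_block_index, ApproxParams(50, 10))
        assert (res.status, res.approx_shift, res.new_pos) == (APPROX, -30, 191)

    def test_unconvertible_when_disabled(self, two_block_index):
        res = convert_probe(Probe("p", "chr1", 121), two_block_index, ApproxParams(0, 10))
        assert (res.status, res.reason) == (UNCONV, Reason.POSITION_UNMAPPED)


class TestFileOperations:
    def test_all_direct_tally(self, identity_index, seg_file):
        path = seg_file([(f"s{i}", "chr1", 10 * i + 1, 10 * i + 5, 7, "0.1") for i in range(10)])
        fr = convert_segment_file(path, identity_index)
        assert fr.tally[DIRECT] == 10
        assert sum(fr.tally.values()) == fr.n_rows == 10

    def test_mixed_fates_partition_row_count(self, two_block_index, seg_file):
        rows = [
            ("a", "chr1", 1, 90, 1, "0.0"),     # direct
            ("b", "chr1", 1, 121, 1, "0.0"),    # approx (end rescued)
            ("c", "chr1", 120, 130, 1, "0.0"),  # both ends rescued to 199: ratio 11 -> rejected
            ("d", "chr9", 1, 50, 1, "0.0"),     # unknown chrom -> unconvertible
        ]
        fr = convert_segment_file(
            seg_file(rows), two_block_index, approx=ApproxParams(30, 10)
        )
        assert sum(fr.tally.values()) == len(rows)
        assert fr.tally[DIRECT] == 1 and fr.tally[APPROX] == 1
        assert fr.tally[REJECTED] == 1 and fr.tally[UNCONV] == 1

    def test_payload_preserved_verbatim(self, identity_index, seg_file, tmp_path):
        from seglift.segments import write_segment_outputs

        path = seg_file([("s", "chr1", 5, 9, "00123", "+0.2500")])
        fr = convert_segment_file(path, identity_index)
        out = tmp_path / "out.seg"
        write_segment_outputs(fr, out, "out.seg")
        assert out.read_text().splitlines()[1] == "s\tchr1\t5\t9\t00123\t+0.2500"

    def test_corrupt_row_recorded_and_skipped(self, identity_index, seg_file):
        path = seg_file([("a", "chr1", 1, 10, 1, "0.0"), ("b", "chr1", "oops", 20, 1, "0.0")])
        fr = convert_segment_file(path, identity_index)
        assert fr.n_rows == 1
        assert len(fr.errors) == 1 and fr.errors[0].line_no == 3

    def test_header_only_file(self, identity_index, seg_file):
        fr = convert_segment_file(seg_file([]), identity_index)
        assert fr.n_rows == 0 and sum(fr.tally.values()) == 0

    def test_probe_file_has_no_rejected_class(self, two_block_index, probe_file):
        rows = [("p1", "chr1", 50, "0.0"), ("p2", "chr1", 121, "0.0"), ("p3", "chr1", 121, "0.0")]
        fr = convert_probe_file(probe_file(rows), two_block_index, ApproxParams(0, 10))
        assert fr.tally[REJECTED] == 0
        assert fr.tally[DIRECT] == 1 and fr.tally[UNCONV] == 2


class TestMonotonicityInRange:
    def test_enlarging_range_never_loses_conversions(self, two_block_index, seg_file):
        rows = [("s%d" % i, "chr1", 1, end, 1, "0.0") for i, end in enumerate(range(101, 150, 4))]
        path = seg_file(rows)
        prev_conv, prev_unconv = -1, 10**9
        for rng in (0, 10, 20, 30, 40, 60):
            fr = convert_segment_file(path, two_block_index, approx=ApproxParams(rng, 10))
            conv = fr.tally[DIRECT] + fr.tally[APPROX]
            assert conv >= prev_conv
            assert fr.tally[UNCONV] <= prev_unconv
            prev_conv, prev_unconv = conv, fr.tally[UNCONV]
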