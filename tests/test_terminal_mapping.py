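"""Flag classification, CIGAR scoring, 5'-end calling and the ambiguity filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccseq import (
    AlignedSegment,
    PairClass,
    ReadSimConfig,
    apply_region_mask,
    call_five_prime,
    classify_pair,
    five_prime_mismatch_run,
    map_read_pairs,
    reference_span,
    simulate_read_pairs,
)
from ccseq import fileio
from ccseq.breakmap import BreakMap, WATSON, CRICK


def seg(flag, leftmost, cigar, md=None, mapq=42, name="q", contig="chr1"):
    return AlignedSegment(name, flag, contig, leftmost, mapq, cigar, md)


def parse_cigar(text):
    out, num = [], ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


class TestClassifyPair:
    @pytest.mark.parametrize(
        "f1,f2,expected",
        [
            (99, 147, PairClass.WATSON_PAIR),
            (83, 163, PairClass.CRICK_PAIR),
            (77, 141, PairClass.REJECT),     # unmapped pair
            (99, 163, PairClass.REJECT),     # inconsistent combination
            (355, 403, PairClass.REJECT),    # secondary alignments
        ],
    )
    def test_flag_combinations(self, f1, f2, expected):
        assert classify_pair(f1, f2) is expected

    def test_symmetric_in_argument_order(self):
        for f1, f2 in [(99, 147), (83, 163), (77, 141)]:
            assert classify_pair(f1, f2) is classify_pair(f2, f1)


class TestReferenceSpan:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ("75M", 75),
            ("35M2D10M3I30M", 77),       # insertions ignored, deletions counted
            ("5M2I30M1D25M", 61),
            ("10S65M", 65),              # soft clips consume no reference
        ],
    )
    def test_scoring_rule(self, cigar, expected):
        assert reference_span(parse_cigar(cigar)) == expected

    def test_unknown_op_is_hard_error(self):
        with pytest.raises(ValueError, match="N"):
            reference_span([(10, "M"), (5, "N")])


class TestCallFivePrime:
    def test_minus_strand_indel_example(self):
        # leftmost 10200, CIGAR 35M2D10M3I30M: 10200 + 35 + 2 + 10 + 30 - 1
        coord, strand = call_five_prime(seg(83, 10200, parse_cigar("35M2D10M3I30M")))
        assert (coord, strand) == (10276, CRICK)

    def test_minus_strand_simple(self):
        coord, strand = call_five_prime(seg(83, 10200, parse_cigar("75M")))
        assert (coord, strand) == (10274, CRICK)

    def test_plus_strand_is_leftmost(self):
        coord, strand = call_five_prime(seg(99, 10200, parse_cigar("75M")))
        assert (coord, strand) == (10200, WATSON)

    def test_against_base_by_base_walk_oracle(self):
        """A literal per-base walk over the reference must agree on random CIGARs."""
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            n_ops = rng.integers(1, 6)
            cigar = []
            for i in range(n_ops):
                op = str(rng.choice(["M", "I", "D", "S"])) if 0 < i < n_ops - 1 else "M"
                cigar.append((int(rng.integers(1, 40)), op))
            leftmost = int(rng.integers(1, 10_000))
            # oracle: touch each reference base one at a time
            ref = leftmost - 1
            for length, op in cigar:
                if op in ("M", "D"):
                    for _base in range(length):
                        ref += 1
            coord, _ = call_five_prime(seg(83, leftmost, cigar))
            assert coord == ref

    @given(
        st.lists(
            st.tuples(st.integers(1, 50), st.sampled_from("MIDS")), min_size=1, max_size=6
        ).filter(lambda c: any(op == "M" for _l, op in c)),
        st.integers(1, 100_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_minus_strand_span_identity(self, cigar, leftmost):
        coord, _ = call_five_prime(seg(83, leftmost, cigar))
        assert coord - leftmost + 1 == reference_span(cigar)


class TestFivePrimeMismatchRun:
    @pytest.mark.parametrize(
        "md,cigar,reverse,expected",
        [
            ("0T0C25A5^T10", "75M", False, 2),   # two terminal substitutions
            ("75", "75M", False, 0),
            ("25A0T0", "75M", True, 2),          # minus: run read from the right
            ("0T74", "75M", False, 1),
            ("0T74", "75M", True, 0),
            ("^AC40", "42M", False, 2),          # terminal deletion counts as absent
            ("65", "10S65M", False, 10),         # 5' soft clip counts toward the run
            ("65", "65M10S", True, 10),
        ],
    )
    def test_run_lengths(self, md, cigar, reverse, expected):
        assert five_prime_mismatch_run(md, parse_cigar(cigar), reverse) == expected

    def test_malformed_md_is_hard_error(self):
        with pytest.raises(ValueError, match="malformed"):
            five_prime_mismatch_run("25A!10", [(36, "M")], False)


def make_pair(contig="chr1", w_pos=500, name="p1", crick=False, md1=None, mapq=42, L=50):
    if crick:
        r1 = seg(83, w_pos - L + 1, parse_cigar(f"{L}M"), md1, mapq, name, contig)
        r2 = seg(163, w_pos - 200, parse_cigar(f"{L}M"), None, mapq, name, contig)
    else:
        r1 = seg(99, w_pos, parse_cigar(f"{L}M"), md1, mapq, name, contig)
        r2 = seg(147, w_pos + 200, parse_cigar(f"{L}M"), None, mapq, name, contig)
    return (r1, r2)


class TestMapReadPairs:
    def test_accumulation_at_read1_five_prime(self):
        pairs = [make_pair(name="a"), make_pair(name="b")]
        bmap, stats = map_read_pairs(pairs)
        assert bmap.counts[("chr1", WATSON)][500] == 2
        assert stats.pairs_counted == 2

    def test_ambiguous_end_excludes_pair(self):
        pairs = [make_pair(name="a", md1="0T0C25A5^T10", L=75), make_pair(name="b", L=75)]
        bmap, stats = map_read_pairs(pairs)
        assert stats.pairs_ambiguous_end == 1
        assert bmap.total_count() == 1

    def test_mapq_filter_applies_to_both_mates(self):
        lowq = make_pair(name="a")
        lowq[1].mapq = 3
        ok = make_pair(name="b")
        bmap, stats = map_read_pairs([lowq, ok], mapq_min=10)
        assert stats.pairs_mapq_rejected == 1
        assert stats.pairs_counted == 1

    def test_mates_on_different_contigs_flag_rejected(self):
        r1, r2 = make_pair(name="x")
        r2.ref_name = "chr2"
        _bmap, stats = map_read_pairs([(r1, r2)])
        assert stats.pairs_flag_rejected == 1

    def test_double_mode_filters_read2_end(self):
        r1, r2 = make_pair(name="x", L=75)
        r2.md_tag = "73A0C0"  # Read-2 of a Watson pair is minus-strand: 5' end is rightmost
        _b, s_single = map_read_pairs([(r1.__class__(**vars(r1)), r2.__class__(**vars(r2)))])
        _b, s_double = map_read_pairs([(r1, r2)], library_mode="double")
        assert s_single.pairs_counted == 1
        assert s_double.pairs_ambiguous_end == 1

    def test_stats_partition_on_mixed_stream(self):
        pairs = [
            make_pair(name="ok"),
            make_pair(name="crick", crick=True),
            make_pair(name="amb", md1="0A0C48"),
        ]
        bad = make_pair(name="bad")
        bad[0].sam_flag = 77
        bad[1].sam_flag = 141
        pairs.append(bad)
        _bmap, stats = map_read_pairs(pairs)
        stats.check()
        assert stats.pairs_seen == 4
        assert stats.pairs_counted == 2

    def test_simulator_round_trip_exact(self, truth_map, clean_sam):
        bmap, stats = map_read_pairs(fileio.read_alignments(clean_sam))
        assert bmap == truth_map
        assert stats.pairs_counted == truth_map.total_count()

    def test_terminal_mismatches_remove_exactly_those_pairs(
        self, truth_map, small_genome
    ):
        """Pairs with 2-bp 5' mismatch runs are filtered; nothing else changes."""
        records = simulate_read_pairs(
            truth_map, small_genome, ReadSimConfig(terminal_mismatch_prob=0.3, seed=77)
        )
        pairs = {}
        for r in records:
            pairs.setdefault(r.qname, []).append(r)
        stream = [
            tuple(
                AlignedSegment(r.qname, r.flag, r.rname, r.pos, r.mapq, parse_cigar(r.cigar), r.md)
                for r in v
            )
            for v in pairs.values()
        ]
        mutated = {
            segs[0].query_name
            for segs in stream
            for s in segs
            if s.is_read1
            and five_prime_mismatch_run(s.md_tag, s.cigar, s.is_reverse) >= 2
        }
        bmap, stats = map_read_pairs(stream)
        assert stats.pairs_ambiguous_end == len(mutated)
        assert stats.pairs_counted + stats.pairs_ambiguous_end == stats.pairs_seen
        assert bmap.total_count() == truth_map.total_count() - len(mutated)


class TestApplyRegionMask:
    def make_map(self):
        bmap = BreakMap(total_mapped_pairs=10)
        for pos in (50, 100, 150, 200, 250):
            bmap.add("chr1", WATSON, pos)
        return bmap

    def test_exclude_drops_inside_positions(self):
        out = apply_region_mask(self.make_map(), [("chr1", 100, 200)], "exclude")
        assert sorted(out.counts[("chr1", WATSON)]) == [50, 200, 250]

    def test_boundary_position_retained_under_half_open_exclude(self):
        out = apply_region_mask(self.make_map(), [("chr1", 100, 200)], "exclude")
        assert 200 in out.counts[("chr1", WATSON)]

    def test_include_keeps_only_inside(self):
        out = apply_region_mask(self.make_map(), [("chr1", 100, 200)], "include")
        assert sorted(out.counts[("chr1", WATSON)]) == [100, 150]

    def test_empty_mask_is_identity(self):
        bmap = self.make_map()
        out = apply_region_mask(bmap, [], "exclude")
        assert out == bmap

    def test_total_mapped_pairs_unchanged(self):
        out = apply_region_mask(self.make_map(), [("chr1", 1, 1000)], "exclude")
        assert out.total_mapped_pairs == 10

    def test_malformed_interval_is_hard_error(self):
        with pytest.raises(ValueError, match="end < start"):
            apply_region_mask(self.make_map(), [("chr1", 200, 100)], "exclude")
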