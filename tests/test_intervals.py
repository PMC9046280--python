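"""Interval arithmetic, the fractional-overlap rule, and set partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulink import (
    GenomicInterval,
    PeakSet,
    UsageError,
    center_window,
    multiway_membership,
    overlap_length,
    partition_sets,
    peaks_overlap,
    read_bed,
    read_narrowpeak,
    write_bed,
    write_narrowpeak,
)

from conftest import random_intervals
from oracles import brute_force_shared_flags


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestOverlapLength:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 0, 100), ("chr1", 40, 100), 60),
            (("chr1", 0, 100), ("chr1", 100, 200), 0),  # half-open abutment
            (("chr1", 0, 100), ("chr2", 0, 100), 0),    # different chromosome
            (("chr1", 10, 20), ("chr1", 0, 100), 10),   # containment
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert overlap_length(iv(*a), iv(*b)) == expected


class TestPeaksOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 0, 100), ("chr1", 40, 100), True),    # 60 > 50
            (("chr1", 0, 100), ("chr1", 90, 200), False),   # 10 <= 50 and <= 55
            (("chr1", 0, 200), ("chr1", 140, 160), True),   # 20 > 10 (half of b)
            (("chr1", 0, 100), ("chr1", 50, 150), False),   # 50 is not > 50: strict
        ],
    )
    def test_either_mode_rule(self, a, b, expected):
        assert peaks_overlap(iv(*a), iv(*b)) is expected

    def test_both_mode_requires_reciprocal_coverage(self):
        a, b = iv("chr1", 0, 200), iv("chr1", 140, 160)
        assert peaks_overlap(a, b, mode="either")
        assert not peaks_overlap(a, b, mode="both")

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_min_frac_domain(self, bad):
        with pytest.raises(UsageError):
            peaks_overlap(iv("chr1", 0, 10), iv("chr1", 0, 10), min_frac=bad)

    @given(
        sa=st.integers(0, 500), wa=st.integers(1, 300),
        sb=st.integers(0, 500), wb=st.integers(1, 300),
        frac=st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, sa, wa, sb, wb, frac):
        a = iv("chr1", sa, sa + wa)
        b = iv("chr1", sb, sb + wb)
        assert peaks_overlap(a, b, frac) == peaks_overlap(b, a, frac)


class TestPartitionSets:
    def test_fully_shared_pair(self):
        a = PeakSet("A", [iv("chr1", 0, 100)])
        b = PeakSet("B", [iv("chr1", 40, 100)])
        part = partition_sets(a, b)
        assert part.shared_a == a.intervals and part.shared_b == b.intervals
        assert part.unique_a == [] and part.unique_b == []

    def test_empty_other_set_makes_everything_unique(self):
        a = PeakSet("A", [iv("chr1", 0, 100), iv("chr2", 5, 50)])
        part = partition_sets(a, PeakSet("B", []))
        assert part.unique_a == a.intervals
        assert part.shared_a == [] and part.unique_b == [] and part.shared_b == []

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        triples_a = random_intervals(rng, 1000)
        triples_b = random_intervals(rng, 1000)
        a = PeakSet("A", [iv(*t) for t in triples_a])
        b = PeakSet("B", [iv(*t) for t in triples_b])
        part = partition_sets(a, b)
        keys_a = [(x.chrom, x.start, x.end) for x in a]
        expect_shared_a = brute_force_shared_flags(keys_a, triples_b)
        got_shared = {(x.chrom, x.start, x.end) for x in part.shared_a}
        for key, flag in zip(keys_a, expect_shared_a):
            assert (key in got_shared) == flag

    def test_partition_covers_input_exactly(self, rng):
        triples = random_intervals(rng, 300)
        a = PeakSet("A", [iv(*t) for t in triples])
        b = PeakSet("B", [iv(*t) for t in random_intervals(rng, 300)])
        part = partition_sets(a, b)
        assert len(part.unique_a) + len(part.shared_a) == len(a)
        assert sorted(part.unique_a + part.shared_a) == a.intervals

    def test_deterministic_sorted_output(self, rng):
        ivs = [iv(*t) for t in random_intervals(rng, 50)]
        part = partition_sets(PeakSet("A", ivs), PeakSet("B", []))
        assert part.unique_a == sorted(
            part.unique_a, key=lambda x: (x.chrom, x.start, x.end)
        )


class TestMultiwayMembership:
    def test_requires_two_sets(self):
        with pytest.raises(UsageError):
            multiway_membership([PeakSet("A", [iv("chr1", 0, 10)])])

    def test_shared_and_unique_profiles(self):
        shared = iv("chr1", 1000, 1400)
        only1 = iv("chr1", 5000, 5400)
        s1 = PeakSet("s1", [shared, only1])
        s2 = PeakSet("s2", [shared])
        s3 = PeakSet("s3", [shared])
        profiles = {
            x.name if x.name else (x.chrom, x.start): p
            for _, x, p in multiway_membership([s1, s2, s3])
        }
        assert profiles[("chr1", 1000)] == (True, True, True)
        # the unique interval appears once, from set 0
        records = [r for r in multiway_membership([s1, s2, s3])
                   if r[1] == only1 and r[0] == 0]
        assert records[0][2] == (True, False, False)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        sets_triples = [random_intervals(rng, 200) for _ in range(3)]
        sets = [PeakSet(f"s{i}", [iv(*t) for t in ts])
                for i, ts in enumerate(sets_triples)]
        for set_idx, interval, profile in multiway_membership(sets):
            key = [(interval.chrom, interval.start, interval.end)]
            for j, triples in enumerate(sets_triples):
                if j == set_idx:
                    assert profile[j] is True
                else:
                    expected = brute_force_shared_flags(key, triples)[0]
                    assert profile[j] == expected


class TestCenterWindow:
    def test_midpoint_window(self):
        win = center_window(iv("chr1", 100, 200), 50, 10**6)
        assert (win.start, win.end) == (100, 200)

    def test_left_clipped(self):
        win = center_window(iv("chr1", 0, 10), 50, 10**6)
        assert (win.start, win.end) == (0, 55)

    def test_summit_takes_precedence_over_midpoint(self):
        win = center_window(iv("chr1", 100, 200, summit_offset=10), 50, 10**6)
        assert (win.start, win.end) == (60, 160)

    @given(
        start=st.integers(0, 5000), width=st.integers(1, 400),
        flank=st.integers(1, 300),
    )
    @settings(max_examples=200, deadline=None)
    def test_window_length_never_exceeds_two_flanks(self, start, width, flank):
        win = center_window(iv("chr1", start, start + width), flank, 6000)
        assert 0 < len(win) <= 2 * flank

    def test_invalid_chrom_length_rejected(self):
        with pytest.raises(UsageError):
            center_window(iv("chr1", 0, 10), 50, 0)


class TestInvariants:
    def test_negative_and_reversed_coordinates_rejected(self):
        for start, end in [(-1, 10), (10, 10), (10, 5)]:
            with pytest.raises(UsageError):
                GenomicInterval("chr1", start, end)

    def test_summit_outside_interval_rejected(self):
        with pytest.raises(UsageError):
            GenomicInterval("chr1", 0, 100, summit_offset=100)


class TestRoundTrip:
    def test_bed_round_trip_is_byte_identical(self, tmp_path, rng):
        ivs = [
            iv(*t, name=f"p{i}", score=float(rng.integers(0, 1000)), strand=".")
            for i, t in enumerate(random_intervals(rng, 40))
        ]
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(p1, ivs)
        write_bed(p2, read_bed(p1))
        assert p1.read_bytes() == p2.read_bytes()

    def test_narrowpeak_round_trip_is_byte_identical(self, tmp_path, rng):
        ivs = [
            GenomicInterval(
                t[0], t[1], t[2], name=f"p{i}",
                score=float(rng.integers(0, 1000)), strand=".",
                summit_offset=(t[2] - t[1]) // 2 if i % 2 else None,
                extra=("4.5", "12.1", "9.33"),
            )
            for i, t in enumerate(random_intervals(rng, 40))
        ]
        p1, p2 = tmp_path / "a.narrowPeak", tmp_path / "b.narrowPeak"
        write_narrowpeak(p1, ivs)
        back = read_narrowpeak(p1)
        assert [x.summit_offset for x in back] == [x.summit_offset for x in ivs]
        write_narrowpeak(p2, back)
        assert p1.read_bytes() == p2.read_bytes()
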