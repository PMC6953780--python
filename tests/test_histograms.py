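"""Unit and property tests for the hierarchical-histogram construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahht.histograms import (
    Bin,
    ChannelHistogram,
    build_hierarchical_histogram,
    channel_merge_threshold,
    compute_level1_histogram,
    find_valleys,
    merge_bell_region,
    next_level_histogram,
    robust_span,
)
from ahht.synthetic import make_toy_histogram


def hist_from_counts(counts, channel="R"):
    """Dense histogram fixture from a raw count sequence."""
    bins = tuple(Bin(int(c), l, l) for l, c in enumerate(counts))
    return ChannelHistogram(
        bins=bins, level=1, channel=channel, total_pixels=int(sum(counts))
    )


def valley_rule_oracle(counts):
    """Literal exhaustive evaluation of the valley rule.

    For every position l and plateau length k: counts drop into l from the
    left, stay equal through l..l+k, and rise after l+k; the valley sits at
    l + floor(k/2). Independent of the scanning implementation under test.
    """
    n = len(counts)
    valleys = set()
    for l in range(1, n):
        for k in range(0, n - l - 1):
            if (
                counts[l] < counts[l - 1]
                and all(counts[l + j] == counts[l] for j in range(k + 1))
                and counts[l + k] < counts[l + k + 1]
            ):
                valleys.add(l + k // 2)
    return sorted(valleys)


class TestLevel1Histogram:
    def test_single_intensity_image(self):
        img = np.full((2, 2, 3), 5, dtype=np.uint8)
        h = compute_level1_histogram(img, "R")
        assert len(h) == 256
        assert h.bins[5].count == 4
        assert sum(b.count for b in h.bins) == 4
        assert all(b.rep_intensity == b.right_endpoint for b in h.bins)

    def test_matches_brute_force_tally(self, rng):
        img = rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8)
        for ch, ci in (("R", 0), ("G", 1), ("B", 2)):
            h = compute_level1_histogram(img, ch)
            for l in range(256):
                expected = sum(
                    1
                    for m in range(4)
                    for n in range(4)
                    if img[m, n, ci] == l
                )
                assert h.bins[l].count == expected

    def test_rejects_float_image(self):
        with pytest.raises(ValueError):
            compute_level1_histogram(np.zeros((2, 2, 3), dtype=float), "R")


class TestFindValleys:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1, 2, 3, 4], []),  # monotone: no local minimum
            ([5, 2, 6], [1]),
            ([5, 2, 2, 2, 6], [2]),  # plateau of 3, midpoint
            ([5, 2, 2, 6], [1]),  # even plateau: left-of-middle
            ([3, 1, 3, 1, 3], [1, 3]),
            ([2, 2, 2], []),  # flat everywhere: no drop
        ],
    )
    def test_hand_cases(self, counts, expected):
        assert find_valleys(hist_from_counts(counts)) == expected

    def test_endpoints_never_valleys(self):
        # a descending-then-flat tail has no right flank
        assert find_valleys(hist_from_counts([5, 1])) == []
        assert find_valleys(hist_from_counts([1, 5])) == []

    @given(
        st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=12)
    )
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_exhaustive_rule(self, counts):
        assert find_valleys(hist_from_counts(counts)) == valley_rule_oracle(counts)


class TestRobustSpan:
    def test_single_intensity(self):
        counts = np.zeros(256, int)
        counts[128] = 50
        assert robust_span(hist_from_counts(counts)) == 0

    def test_trim_boundary_is_strict(self):
        # mass exactly equal to the trim fraction does not count as inside
        counts = np.zeros(256, int)
        counts[0], counts[50], counts[150] = 1, 49, 50
        assert robust_span(hist_from_counts(counts), trim_fraction=0.01) == 100

    def test_zero_trim_is_plain_span(self):
        counts = np.zeros(256, int)
        counts[10], counts[200] = 3, 7
        assert robust_span(hist_from_counts(counts), trim_fraction=0.0) == 190

    def test_empty_histogram_errors(self):
        with pytest.raises(ValueError):
            robust_span(hist_from_counts(np.zeros(256, int)))


class TestChannelMergeThreshold:
    @pytest.mark.parametrize(
        "w, span, expected",
        [(15, 255, 15 * 255 / 256), (15, 0, 0.0), (15, 100, 5.859375)],
    )
    def test_values(self, w, span, expected):
        assert channel_merge_threshold(w, span) == pytest.approx(expected)


class TestMergeBellRegion:
    def test_single_bin_unchanged(self):
        h = hist_from_counts([0, 0, 7])
        assert merge_bell_region(h, 2, 2, 10.0) == [Bin(7, 2, 2)]

    def test_weighted_mean_rounds_half_up(self):
        bins = (Bin(4, 10, 10), Bin(6, 12, 12))
        h = ChannelHistogram(bins=bins, level=2, channel="R", total_pixels=10)
        out = merge_bell_region(h, 0, 1, 20.0)
        assert out == [Bin(10, 11, 12)]  # (4*10 + 6*12)/10 = 11.2 -> 11

    def test_span_criterion_group_bound(self):
        bins = (Bin(5, 0, 0), Bin(5, 10, 10), Bin(5, 20, 20))
        h = ChannelHistogram(bins=bins, level=2, channel="R", total_pixels=15)
        out = merge_bell_region(h, 0, 2, 15.0)
        assert [b.count for b in out] == [10, 5]
        assert len(out) <= (20 - 0) // 15 + 1

    def test_out_of_range_indices(self):
        h = hist_from_counts([1, 2])
        with pytest.raises(IndexError):
            merge_bell_region(h, 0, 5, 1.0)

    @given(
        counts=st.lists(st.integers(0, 5), min_size=2, max_size=30),
        w_i=st.floats(min_value=0.5, max_value=40.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_output_bin_count_bound(self, counts, w_i):
        h = hist_from_counts(counts)
        out = merge_bell_region(h, 0, len(counts) - 1, w_i)
        span = len(counts) - 1
        assert len(out) <= int(span / w_i) + 1
        assert sum(b.count for b in out) == sum(counts)


class TestNextLevelHistogram:
    def test_no_valleys_merges_to_one_bin(self):
        h = hist_from_counts([0, 3, 5, 3, 0])
        out = next_level_histogram(h, [], w_i=10.0)
        assert len(out) == 1
        assert out.bins[0].count == 11
        assert out.level == 2

    def test_valley_splits_regions(self):
        h = hist_from_counts([5, 2, 6])
        out = next_level_histogram(h, [1], w_i=100.0)
        assert out.bins == (Bin(7, 0, 1), Bin(6, 2, 2))

    def test_unknown_valley_rejected(self):
        h = hist_from_counts([5, 2, 6])
        with pytest.raises(ValueError):
            next_level_histogram(h, [7], w_i=10.0)

    @given(
        counts=st.lists(st.integers(0, 4), min_size=3, max_size=20).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, counts):
        h = hist_from_counts(counts)
        out = next_level_histogram(h, find_valleys(h), w_i=3.0)
        assert sum(b.count for b in out.bins) == sum(counts)


class TestBuildHierarchy:
    def test_uniform_image_collapses_to_one_bin(self, uniform_image):
        hh = build_hierarchical_histogram(uniform_image)
        for ch in "RGB":
            assert len(hh.top(ch)) == 1
            assert hh.top(ch).bins[0].count == 256
            assert hh.w_i[ch] == 0.0

    def test_two_mode_channel_yields_two_top_bins(self, rng):
        n = 3200
        # truncated at 3 sigma: isolated tail pixels beyond the merge budget
        # would legitimately keep their own bins
        vals = np.concatenate(
            [
                np.clip(rng.normal(40, 4, n // 2), 28, 52),
                np.clip(rng.normal(200, 4, n // 2), 188, 212),
            ]
        )
        plane = np.clip(np.floor(vals + 0.5), 0, 255).astype(np.uint8)
        img = np.zeros((40, 80, 3), dtype=np.uint8)
        img[:, :, 0] = plane.reshape(40, 80)
        hh = build_hierarchical_histogram(img)
        top = hh.top("R")
        assert len(top) == 2
        reps = top.rep_intensities
        assert abs(reps[0] - 40) <= 2 and abs(reps[1] - 200) <= 2

    def test_every_level_conserves_pixels(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        hh = build_hierarchical_histogram(img)
        for ch in "RGB":
            for level in hh.levels[ch]:
                assert sum(b.count for b in level.bins) == 32 * 32

    def test_bin_count_non_increasing_with_level(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        hh = build_hierarchical_histogram(img)
        for ch in "RGB":
            sizes = [len(h) for h in hh.levels[ch]]
            assert sizes == sorted(sizes, reverse=True)

    def test_fixed_point_reached(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        hh = build_hierarchical_histogram(img)
        from ahht.histograms import find_valleys as fv, next_level_histogram as nl

        for ch in "RGB":
            top = hh.top(ch)
            again = nl(top, fv(top), hh.w_i[ch])
            assert again.bins == top.bins

    def test_toy_two_mode_histogram_has_single_valley(self):
        h = make_toy_histogram([(60, 500, 10), (180, 500, 10)])
        valleys = find_valleys(h)
        assert len(valleys) == 1
        assert 70 < valleys[0] < 170
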