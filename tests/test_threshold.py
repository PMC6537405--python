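"""Yen thresholding, the central-slice rule, and the signal-absence rule."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellfate3d.errors import NoContrastError
from cellfate3d.image_io import ChannelRole
from cellfate3d.threshold import (
    Histogram, apply_signal_rule, central_slice_indices, estimate_stack_threshold,
    histogram_from_planes, robust_background_threshold, segment_foreground,
    yen_threshold,
)
from cellfate3d.synthetic import SceneParams, simulate_scene

from conftest import analyze_channel


def yen_bruteforce(counts, edges):
    """Independent oracle: exhaustive loop over every interior cut."""
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    best_tc, best_edge = -np.inf, None
    for i in range(len(p) - 1):
        p1, p2 = p[: i + 1].sum(), p[i + 1:].sum()
        s1, s2 = (p[: i + 1] ** 2).sum(), (p[i + 1:] ** 2).sum()
        if min(p1, p2, s1, s2) <= 0:
            continue
        tc = -math.log(s1 * s2 / (p1 ** 2 * p2 ** 2))
        if tc > best_tc:
            best_tc, best_edge = tc, edges[i + 1]
    return best_edge


def random_histogram(rng, n_bins):
    counts = rng.integers(0, 1000, size=n_bins)
    while np.count_nonzero(counts) < 2:
        counts = rng.integers(0, 1000, size=n_bins)
    edges = np.linspace(0, float(rng.integers(100, 5000)), n_bins + 1)
    return Histogram(counts=counts, bin_edges=edges)


class TestYen:
    def test_matches_exhaustive_oracle_on_100_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            hist = random_histogram(rng, int(rng.integers(8, 257)))
            assert yen_threshold(hist) == yen_bruteforce(hist.counts, hist.bin_edges)

    def test_two_delta_histogram_separates_the_bright_class(self):
        pixels = np.array([10.0] * 500 + [200.0] * 500)
        hist = histogram_from_planes([pixels.reshape(25, 40)])
        t = yen_threshold(hist)
        assert 10 < t < 200
        assert ((pixels > t) == (pixels == 200)).all()

    def test_single_valued_histogram_raises_no_contrast(self):
        hist = Histogram(counts=[0, 50, 0], bin_edges=[0, 1, 2, 3])
        with pytest.raises(NoContrastError):
            yen_threshold(hist)

    def test_agrees_with_independent_library_implementation(self):
        # same pixel data through skimage's Yen: thresholds should land
        # within one bin of each other (edge vs center conventions differ)
        from skimage.filters import threshold_yen

        rng = np.random.default_rng(7)
        img = np.concatenate([
            rng.normal(100, 10, 4000), rng.normal(900, 60, 400)
        ]).clip(0).reshape(40, 110)
        hist = histogram_from_planes([img])
        width = hist.bin_edges[1] - hist.bin_edges[0]
        assert abs(yen_threshold(hist) - threshold_yen(img, nbins=256)) <= width

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        hist = random_histogram(rng, int(rng.integers(4, 129)))
        assert yen_threshold(hist) == yen_bruteforce(hist.counts, hist.bin_edges)

    def test_scale_equivariance_rescales_threshold_and_preserves_masks(self):
        rng = np.random.default_rng(3)
        plane = np.concatenate([
            rng.normal(50, 8, 3000), rng.normal(600, 40, 300)
        ]).clip(0).reshape(55, 60)
        c = 3.0
        t1 = yen_threshold(histogram_from_planes([plane]))
        t3 = yen_threshold(histogram_from_planes([plane * c]))
        assert t3 == pytest.approx(c * t1, rel=1e-12)
        np.testing.assert_array_equal(plane > t1, plane * c > t3)

    def test_raising_threshold_never_adds_foreground(self):
        rng = np.random.default_rng(4)
        plane = rng.uniform(0, 1000, (50, 50))
        masks = [plane > t for t in (100, 300, 500, 700)]
        for lo, hi in zip(masks, masks[1:]):
            assert not (hi & ~lo).any()


class TestCentralSlices:
    @pytest.mark.parametrize(
        "n,fraction,expected",
        [(5, 0.2, [2]), (12, 0.2, [4, 5, 6]), (10, 0.2, [4, 5]),
         (1, 0.2, [0]), (4, 1.0, [0, 1, 2, 3]), (251, 0.2, list(range(100, 151)))],
    )
    def test_centered_block_arithmetic(self, n, fraction, expected):
        assert central_slice_indices(n, fraction) == expected

    def test_blank_stack_has_no_signal(self, blank_scene):
        _, decision, masks = analyze_channel(blank_scene, ChannelRole.NUCLEAR)
        assert not decision.has_signal
        assert masks.sum() == 0

    def test_nuclei_stack_mask_recovers_planted_foreground(self, nuclei_scene):
        _, decision, masks = analyze_channel(nuclei_scene, ChannelRole.NUCLEAR)
        gt = nuclei_scene.ground_truth[ChannelRole.NUCLEAR]
        assert decision.has_signal
        jaccard = (masks & gt).sum() / (masks | gt).sum()
        assert jaccard >= 0.8
        assert masks.sum() == pytest.approx(gt.sum(), rel=0.15)

    def test_no_contrast_degrades_to_signal_absent_not_error(self):
        stack = np.zeros((4, 16, 16))
        decision = estimate_stack_threshold(stack)
        assert not decision.has_signal and math.isinf(decision.threshold)


class TestSignalRule:
    @pytest.mark.parametrize(
        "threshold,background,expected",
        [(1000, 50, True),   # 20-fold
         (90, 10, False),    # 9-fold: less than ten-fold fails
         (100, 10, True)],   # exactly ten-fold passes
    )
    def test_ten_fold_boundary(self, threshold, background, expected):
        assert apply_signal_rule(threshold, background) is expected

    def test_zero_background_always_passes(self):
        assert apply_signal_rule(5.0, 0.0)

    def test_negative_background_rejected(self):
        with pytest.raises(ValueError):
            apply_signal_rule(100, -1)


class TestSegment:
    def test_no_signal_means_empty_mask(self):
        decision = estimate_stack_threshold(np.zeros((3, 8, 8)))
        plane = np.full((8, 8), 1e6)
        assert segment_foreground(plane, decision).sum() == 0

    def test_plane_equal_to_threshold_is_background(self, nuclei_scene):
        _, decision, _ = analyze_channel(nuclei_scene, ChannelRole.NUCLEAR)
        plane = np.full((8, 8), decision.threshold)
        assert segment_foreground(plane, decision).sum() == 0


class TestRobustBackground:
    def test_matches_bruteforce_trimmed_statistics_on_gaussian_noise(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(100, 10, 1_000_000).clip(0)
        hist = histogram_from_planes([samples.reshape(1000, 1000)])
        t = robust_background_threshold(hist, trim_fraction=0.05, k_sd=2)
        s = np.sort(samples)
        k = int(0.05 * len(s))
        trimmed = s[k:len(s) - k]
        expected = trimmed.mean() + 2 * trimmed.std()
        assert t == pytest.approx(expected, rel=0.02)

    def test_degenerate_all_equal_returns_that_value(self):
        hist = Histogram(counts=[0, 100, 0], bin_edges=[6.0, 6.5, 7.5, 8.0])
        assert robust_background_threshold(hist) == pytest.approx(7.0)

    def test_two_delta_histogram_keeps_only_the_bright_class(self):
        pixels = np.array([10.0] * 900 + [500.0] * 100)
        hist = histogram_from_planes([pixels.reshape(20, 50)])
        t = robust_background_threshold(hist)
        assert 10 < t < 500

    def test_too_few_pixels_rejected(self):
        hist = Histogram(counts=[3, 3], bin_edges=[0, 1, 2])
        with pytest.raises(ValueError):
            robust_background_threshold(hist)


def test_stack_threshold_excludes_edge_slice_halos():
    """One threshold from the central slices, applied stack-wide, leaves the
    dim out-of-focus halos in the extreme slices below threshold."""
    scene = simulate_scene(SceneParams(
        n_cells=15, volume_shape=(8, 160, 160), seed=0, z_range=(3.0, 4.0)))
    _, decision, masks = analyze_channel(scene, ChannelRole.NUCLEAR)
    edge = [0, 1, 6, 7]
    assert scene.ground_truth[ChannelRole.NUCLEAR][edge].sum() == 0
    assert masks[edge].sum() / masks.sum() < 0.05
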