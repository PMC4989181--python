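"""Ratio images, threshold segmentation, size histograms and contribution curves."""

import numpy as np
import pytest

from wormcars import (
    AnalysisParams,
    BandFrame,
    area_contribution,
    normalized_spectrum,
    ratio_image,
    region_contrast,
    segment_accumulations,
    total_area,
)
from wormcars.synthetic import PIXEL_AREA, PIXEL_SIZE

pytestmark = pytest.mark.filterwarnings("error")


def _frame(data, wavenumber=2845.0, pixel_size=1.0):
    return BandFrame(wavenumber, np.asarray(data), pixel_size)


class TestRatioImage:
    def test_uniform_frame_over_buffer_mean(self):
        frame = _frame(np.full((8, 8), 200))
        buf = np.zeros((8, 8), bool)
        buf[:2] = True
        frame.data[buf] = 100
        out = ratio_image(frame, buf)
        assert np.allclose(out[~buf], 2.0) and np.allclose(out[buf], 1.0)

    def test_buffer_self_normalizes_to_one(self):
        frame = _frame(np.random.default_rng(0).integers(50, 150, (16, 16)))
        buf = np.ones((16, 16), bool)
        assert ratio_image(frame, buf)[buf].mean() == pytest.approx(1.0)

    def test_blob_on_field_gives_direct_division(self):
        data = np.full((10, 10), 400)
        data[4:6, 4:6] = 1000
        buf = np.zeros((10, 10), bool)
        buf[0] = True
        out = ratio_image(_frame(data), buf)
        assert np.allclose(out[4:6, 4:6], 2.5)

    def test_empty_or_zero_buffer_is_an_error(self):
        frame = _frame(np.ones((4, 4)))
        with pytest.raises(ValueError, match="empty"):
            ratio_image(frame, np.zeros((4, 4), bool))
        zero = _frame(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="positive"):
            ratio_image(zero, np.ones((4, 4), bool))


class TestRegionContrast:
    def test_region_equals_buffer_gives_one(self):
        frame = _frame(np.random.default_rng(1).integers(10, 90, (8, 8)))
        m = np.ones((8, 8), bool)
        assert region_contrast(frame, m, m) == pytest.approx(1.0)

    def test_hand_mean_ratio(self):
        data = np.array([[4, 6], [2, 3]])
        region = np.array([[True, True], [False, False]])
        buf = ~region
        assert region_contrast(_frame(data), region, buf) == pytest.approx(2.0)

    def test_empty_mask_is_an_error(self):
        frame = _frame(np.ones((4, 4)))
        with pytest.raises(ValueError):
            region_contrast(frame, np.zeros((4, 4), bool), np.ones((4, 4), bool))


class TestSegmentation:
    def test_subthreshold_raster_yields_nothing(self):
        out = segment_accumulations(np.ones((32, 32)), np.ones((32, 32), bool),
                                    AnalysisParams(), PIXEL_SIZE)
        assert out == []

    def test_small_block_is_filtered_by_min_area(self):
        ratio = np.ones((32, 32))
        ratio[5:10, 5:10] = 2.0          # 25 px ≈ 1.90 um² < 10
        out = segment_accumulations(ratio, np.ones((32, 32), bool),
                                    AnalysisParams(), PIXEL_SIZE)
        assert out == []

    def test_block_above_min_area_is_kept_with_correct_area(self):
        ratio = np.ones((32, 32))
        ratio[5:17, 5:17] = 2.0          # 144 px
        out = segment_accumulations(ratio, np.ones((32, 32), bool),
                                    AnalysisParams(), PIXEL_SIZE)
        assert len(out) == 1
        assert out[0].area == pytest.approx(144 * PIXEL_AREA)
        assert out[0].area == pytest.approx(10.92, abs=0.01)
        assert out[0].mean_ratio == pytest.approx(2.0)

    def test_mismatched_shapes_are_an_error(self):
        with pytest.raises(ValueError, match="shape"):
            segment_accumulations(np.ones((8, 8)), np.ones((9, 8), bool))

    def test_widening_ratio_window_never_decreases_total_area(self, rng):
        ratio = 1.0 + 2.5 * rng.random((64, 64))
        eligible = np.ones((64, 64), bool)
        narrow = AnalysisParams(ratio_low=1.8, ratio_high=2.6, min_area=0.1)
        wide = AnalysisParams(ratio_low=1.5, ratio_high=3.0, min_area=0.1)
        t_narrow = total_area(segment_accumulations(ratio, eligible, narrow, 1.0))
        t_wide = total_area(segment_accumulations(ratio, eligible, wide, 1.0))
        assert t_wide >= t_narrow

    def test_raising_min_area_never_increases_total_area(self, rng):
        ratio = np.where(rng.random((64, 64)) < 0.3, 2.0, 1.0)
        eligible = np.ones((64, 64), bool)
        totals = [
            total_area(segment_accumulations(
                ratio, eligible, AnalysisParams(min_area=m), 1.0))
            for m in (1.0, 5.0, 20.0, 80.0)
        ]
        assert all(b <= a for a, b in zip(totals, totals[1:]))


class TestTotalArea:
    def test_empty_is_zero(self):
        assert total_area([]) == 0.0

    def test_sums_component_areas(self):
        ratio = np.ones((64, 64))
        ratio[2:14, 2:14] = 2.0
        ratio[30:50, 30:50] = 2.0
        recs = segment_accumulations(ratio, np.ones((64, 64), bool),
                                     AnalysisParams(), PIXEL_SIZE)
        assert total_area(recs) == pytest.approx((144 + 400) * PIXEL_AREA)

    def test_noiseless_render_total_matches_planted(self, noiseless_render):
        from wormcars import analyze_worm
        recs = analyze_worm(noiseless_render.image_set)
        truth = noiseless_render.truth.blobs
        detectable = truth[
            (truth.area_um2 >= 10.0)
            & truth.contrast_realized.between(1.47, 3.12)].area_um2.sum()
        assert total_area(recs) == pytest.approx(detectable, abs=PIXEL_AREA)


class TestAreaContribution:
    def test_empty_pool_gives_zero_curve(self):
        curve = area_contribution([], 3, AnalysisParams())
        assert curve.integral() == 0.0 and curve.freq_per_worm.sum() == 0.0

    def test_hand_computed_curve(self):
        curve = area_contribution([30.0, 50.0, 50.0], 2, AnalysisParams())
        # bins [0,20) [20,40) [40,60): freq {0, .5, 1}, contribution {0, 15, 50}
        assert np.allclose(curve.freq_per_worm, [0.0, 0.5, 1.0])
        assert np.allclose(curve.contribution_per_worm, [0.0, 15.0, 50.0])
        assert curve.integral() == pytest.approx(65.0)          # = 130/2 exactly
        assert curve.integral() == pytest.approx(130.0 / 2)

    def test_conservation_within_midpoint_binning_bound(self, rng):
        areas = rng.uniform(1.0, 180.0, size=200)
        n_worms = 8
        params = AnalysisParams()
        curve = area_contribution(areas, n_worms, params)
        err = abs(curve.integral() - areas.sum() / n_worms)
        n_bins = len(curve.freq_per_worm)
        bound = n_bins * (params.bin_width / 2) * curve.freq_per_worm.max()
        assert err <= bound

    def test_exact_on_midpoint_aligned_areas(self, rng):
        mids = 20.0 * rng.integers(0, 8, size=50) + 10.0
        curve = area_contribution(mids, 5, AnalysisParams())
        assert curve.integral() == pytest.approx(mids.sum() / 5, rel=1e-12)

    def test_fraction_below_cutoff(self):
        curve = area_contribution([10.0, 30.0, 30.0, 90.0], 1, AnalysisParams())
        total = 10 + 30 + 30 + 90
        assert curve.fraction_below(80.0) == pytest.approx(70.0 / total)
        assert curve.fraction_below(1e9) == pytest.approx(1.0)

    def test_nonpositive_worm_count_is_an_error(self):
        with pytest.raises(ValueError):
            area_contribution([1.0], 0, AnalysisParams())


class TestNormalizedSpectrum:
    def _stack(self, means):
        return [_frame(np.full((6, 6), m), wavenumber=2800.0 + 10 * i)
                for i, m in enumerate(means)]

    def test_peak_normalizes_to_one(self):
        out = normalized_spectrum(self._stack([2, 4, 8]), np.ones((6, 6), bool))
        assert [v for _, v in out] == pytest.approx([0.25, 0.5, 1.0])

    def test_uniform_stack_is_all_ones(self):
        out = normalized_spectrum(self._stack([5, 5, 5]), np.ones((6, 6), bool))
        assert all(v == pytest.approx(1.0) for _, v in out)

    def test_errors(self):
        with pytest.raises(ValueError, match="two frames"):
            normalized_spectrum(self._stack([1]), np.ones((6, 6), bool))
        frames = self._stack([1, 2])
        frames[1].wavenumber = frames[0].wavenumber
        with pytest.raises(ValueError, match="increasing"):
            normalized_spectrum(frames, np.ones((6, 6), bool))
        with pytest.raises(ValueError, match="empty"):
            normalized_spectrum(self._stack([1, 2]), np.zeros((6, 6), bool))


def test_wild_type_size_distribution_shape():
    """Pooled wild-type accumulations: dominant size bin in 20–60 μm² and
    roughly 72% of the area contribution from accumulations < 80 μm²."""
    from wormcars import analyze_worm, render_worm

    areas: list[float] = []
    n_worms = 15
    for s in np.random.default_rng(57).integers(0, 2**31 - 1, n_worms):
        result = render_worm("N2", int(s))
        areas += [r.area for r in analyze_worm(result.image_set)]
    curve = area_contribution(areas, n_worms, AnalysisParams())
    dominant = int(np.argmax(curve.freq_per_worm))
    assert 20.0 <= curve.bin_edges[dominant] and curve.bin_edges[dominant + 1] <= 60.0
    assert curve.fraction_below(80.0) == pytest.approx(0.72, abs=0.10)


def test_params_invariants():
    with pytest.raises(ValueError):
        AnalysisParams(ratio_low=3.2, ratio_high=3.1)
    with pytest.raises(ValueError):
        AnalysisParams(min_area=0.0)
    with pytest.raises(ValueError):
        AnalysisParams(connectivity=3)
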