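"""Integrated oocyte signals, Δ-references, carrier–lipid fit and geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from wormcars import (
    BandFrame,
    OocyteMeasurement,
    axes_from_mask,
    carrier_lipid_fit,
    delta_signals,
    integrated_cars,
    integrated_gfp,
    measure_oocytes,
    normalize_lipid,
    oocyte_volume,
)


def _frame(data):
    return BandFrame(2845.0, np.asarray(data), 1.0)


class TestIntegratedCars:
    def test_uniform_at_background_is_zero(self):
        data = np.full((6, 6), 40)
        oocyte = np.ones((6, 6), bool)
        nucleus = np.zeros((6, 6), bool)
        nucleus[2:4, 2:4] = True
        assert integrated_cars(_frame(data), oocyte, nucleus) == 0.0

    def test_hand_evaluated_sqrt_sum(self):
        # oocyte pixels {5, 5, 10, 1}, nucleus pixel {1}: B = 1 → √4+√4+√9+√0 = 7
        data = np.array([[5, 5], [10, 1]])
        oocyte = np.ones((2, 2), bool)
        nucleus = np.array([[False, False], [False, True]])
        assert integrated_cars(_frame(data), oocyte, nucleus) == pytest.approx(7.0)

    def test_doubling_pixel_count_doubles_signal(self):
        base = np.full((4, 8), 50)
        base[0, 0] = 10                          # nucleus pixel defines B = 10
        nucleus = np.zeros((4, 8), bool)
        nucleus[0, 0] = True
        half = np.zeros((4, 8), bool)
        half[:2] = True
        full = np.ones((4, 8), bool)
        s_half = integrated_cars(_frame(base), half | nucleus, nucleus)
        s_full = integrated_cars(_frame(base), full, nucleus)
        n_half, n_full = (half | nucleus).sum() - 1, full.sum() - 1
        assert s_full / s_half == pytest.approx(n_full / n_half)

    def test_monotone_in_pixel_intensity(self, rng):
        data = rng.integers(10, 200, (8, 8)).astype(float)
        oocyte = np.ones((8, 8), bool)
        nucleus = np.zeros((8, 8), bool)
        nucleus[0, :2] = True
        before = integrated_cars(_frame(data), oocyte, nucleus)
        data2 = data.copy()
        data2[5, 5] += 30                        # raise one non-nucleus pixel
        after = integrated_cars(_frame(data2), oocyte, nucleus)
        assert after >= before

    def test_nucleus_outside_oocyte_is_an_error(self):
        data = np.ones((4, 4))
        oocyte = np.zeros((4, 4), bool)
        oocyte[:2] = True
        nucleus = np.zeros((4, 4), bool)
        nucleus[3, 3] = True
        with pytest.raises(ValueError, match="contained"):
            integrated_cars(_frame(data), oocyte, nucleus)

    def test_noiseless_render_recovers_planted_lipid(self, noiseless_render):
        iset = noiseless_render.image_set
        frame = iset.band(2845.0)
        truth = noiseless_render.truth.oocytes.set_index("position")
        for pos in (-5, -4, -3, -2, -1):
            got = integrated_cars(frame, iset.oocyte_mask(pos), iset.nucleus_mask(pos))
            assert got == pytest.approx(truth.loc[pos, "lipid_realized"], rel=1e-12)
            assert got == pytest.approx(truth.loc[pos, "lipid"], rel=2e-3)


class TestIntegratedGfp:
    def test_hand_sum(self):
        gfp = np.array([[3.0, 7.0], [2.0, 2.0]])
        oocyte = np.array([[True, True], [False, False]])
        neg = ~oocyte
        assert integrated_gfp(gfp, oocyte, neg) == pytest.approx(6.0)   # 1 + 5

    def test_background_equal_signal_is_zero(self):
        gfp = np.full((4, 4), 9.0)
        m = np.zeros((4, 4), bool)
        m[:2] = True
        assert integrated_gfp(gfp, m, ~m) == 0.0

    def test_zero_background_is_plain_sum(self):
        gfp = np.zeros((4, 4))
        gfp[2:, 2:] = 5.0
        neg = np.zeros((4, 4), bool)
        neg[0] = True
        oocyte = np.zeros((4, 4), bool)
        oocyte[2:, 2:] = True
        assert integrated_gfp(gfp, oocyte, neg) == pytest.approx(20.0)


class TestDeltaSignals:
    def _m(self, pos, cars, gfp=None):
        return OocyteMeasurement("w", pos, cars, gfp)

    def test_reference_oocyte_is_zero_and_subtraction(self):
        deltas = delta_signals([self._m(-5, 10.0, 2.0), self._m(-1, 25.0, 8.0)])
        assert deltas[-5] == (0.0, 0.0)
        assert deltas[-1] == (15.0, 6.0)

    def test_all_equal_gives_all_zero(self):
        deltas = delta_signals([self._m(p, 4.0, 1.0) for p in (-5, -4, -3, -2, -1)])
        assert all(v == (0.0, 0.0) for v in deltas.values())

    def test_missing_reference_is_an_error(self):
        with pytest.raises(ValueError, match="-5"):
            delta_signals([self._m(-1, 1.0)])


class TestCarrierLipidFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = carrier_lipid_fit(x, 2 * x + 5)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_covariance_gives_zero_r_squared(self):
        fit = carrier_lipid_fit([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_matches_closed_form_ols_oracle(self, rng):
        x = rng.normal(size=9)
        y = 1.7 * x - 0.4 + 0.3 * rng.normal(size=9)
        fit = carrier_lipid_fit(x, y)
        # closed-form least squares, computed independently
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - slope * x - intercept
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)
        assert fit.r_squared == pytest.approx(r2, rel=1e-9)

    def test_zero_variance_carrier_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            carrier_lipid_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGeometry:
    def test_unit_cylinder(self):
        assert oocyte_volume(1.0, 2.0) == pytest.approx(math.pi)

    def test_reported_minus1_geometry(self):
        assert oocyte_volume(50.9, 22.4) == pytest.approx(2.006e4, rel=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(stn.floats(0.1, 100), stn.floats(0.1, 100), stn.floats(0.1, 10))
    def test_volume_scales_with_cube_of_isotropic_factor(self, length, width, k):
        v1 = oocyte_volume(length, width)
        vk = oocyte_volume(k * length, k * width)
        assert vk == pytest.approx(k ** 3 * v1, rel=1e-9)

    def test_nonpositive_dimensions_are_an_error(self):
        with pytest.raises(ValueError):
            oocyte_volume(0.0, 1.0)

    def test_rectangle_extents(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 20:40] = True                # 40 × 20 px
        length, width = axes_from_mask(mask, 1.0)
        assert length == pytest.approx(40.0, rel=0.01)
        assert width == pytest.approx(20.0, rel=0.01)

    def test_disk_is_isotropic(self):
        from skimage.draw import disk
        mask = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 15.0)
        mask[rr, cc] = True
        length, width = axes_from_mask(mask, 1.0)
        assert length == pytest.approx(2 * 15.0, rel=0.05)
        assert width == pytest.approx(length, rel=0.05)

    def test_rotation_leaves_axes_unchanged(self):
        from skimage.draw import ellipse
        a, b = 90.0, 40.0      # oocyte-scale mask: discretization error ~1 px
        out = []
        for rot in (0.0, 0.4, 1.1):
            mask = np.zeros((256, 256), bool)
            rr, cc = ellipse(128, 128, a, b, rotation=rot)
            mask[rr, cc] = True
            out.append(axes_from_mask(mask, 1.0))
        ref_length, ref_width = out[0]
        assert ref_length == pytest.approx(2 * a, abs=2.0)
        assert ref_width == pytest.approx(2 * b, abs=2.0)
        for length, width in out[1:]:
            assert length == pytest.approx(ref_length, rel=0.05)
            assert width == pytest.approx(ref_width, rel=0.05)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            axes_from_mask(np.zeros((4, 4), bool), 1.0)


class TestNormalizeLipid:
    def _table(self):
        return pd.DataFrame({
            "strain": ["N2", "N2", "fat-2", "fat-2"],
            "position": [-1, -2, -1, -2],
            "mean": [4.0, 2.0, 3.0, 1.0],
            "sem": [0.4, 0.2, 0.3, 0.1],
        })

    def test_reference_cell_becomes_one(self):
        out = normalize_lipid(self._table())
        ref = out[(out.strain == "N2") & (out.position == -1)]["mean"].iloc[0]
        assert ref == pytest.approx(1.0)

    def test_ratios_and_sems_scale_together(self):
        out = normalize_lipid(self._table())
        f2 = out[(out.strain == "fat-2") & (out.position == -1)]
        assert f2["mean"].iloc[0] == pytest.approx(0.75)
        assert f2["sem"].iloc[0] == pytest.approx(0.3 / 4.0)

    def test_all_equal_table_is_all_ones(self):
        t = self._table()
        t["mean"] = 5.0
        out = normalize_lipid(t)
        assert np.allclose(out["mean"], 1.0)

    def test_missing_reference_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_lipid(self._table(), reference=("fat-9", -1))


def test_measure_oocytes_returns_five_staged_rows(n2_render):
    ms = measure_oocytes(n2_render.image_set)
    assert [m.position for m in ms] == [-5, -4, -3, -2, -1]
    cars = [m.integrated_cars for m in ms]
    assert all(b > a for a, b in zip(cars, cars[1:]))       # queue accumulates lipid
    assert all(m.volume == pytest.approx(
        math.pi * m.length * (m.width / 2) ** 2) for m in ms)
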