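"""Pearson, Mander's and Costes-threshold behaviour, including agreement
with independent naive-loop oracles."""

import numpy as np
import pytest

from coloctop import (coloc_per_cell, costes_threshold, manders, pearson,
                      simulate_field)
from coloctop.segment import CellMask

from conftest import field_from_arrays, make_params, noisy_overrides
from oracles import costes_naive, manders_naive, pearson_naive


class TestPearson:
    def test_identical_channels_correlate_perfectly(self):
        img = np.arange(16).reshape(4, 4)
        assert pearson(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_channels(self):
        img = np.arange(16).reshape(4, 4)
        assert pearson(img, 100 - img) == pytest.approx(-1.0, abs=1e-12)

    def test_four_pixel_worked_example(self):
        # r([1,2,3,4],[2,1,4,3]) = 0.6 by direct evaluation of the formula
        r = pearson(np.array([[1, 2], [3, 4]]), np.array([[2, 1], [4, 3]]))
        assert r == pytest.approx(0.6, abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 255, size=(12, 12)).astype(float)
        y = rng.integers(0, 255, size=(12, 12)).astype(float)
        base = pearson(x, y)
        for a, b in [(2.0, 5.0), (0.01, 1000.0), (37.5, -4.0)]:
            assert pearson(a * x + b, y) == pytest.approx(base, abs=1e-12)
            assert pearson(x, a * y + b) == pytest.approx(base, abs=1e-12)

    def test_constant_channel_is_flagged_undefined(self):
        assert np.isnan(pearson(np.full((3, 3), 7), np.arange(9).reshape(3, 3)))

    def test_empty_region_raises(self):
        img = np.ones((3, 3))
        with pytest.raises(ValueError, match="empty region"):
            pearson(img, img, region=np.zeros((3, 3), bool))


class TestManders:
    def test_worked_example(self):
        red = np.array([10, 10, 0, 0])
        green = np.array([5, 0, 5, 0])
        m1, m2 = manders(red, green, t_red=0, t_green=0)
        assert m1 == pytest.approx(0.5, abs=1e-12)
        assert m2 == pytest.approx(0.5, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        red = np.array([1, 1, 0, 0])
        green = np.array([0, 0, 1, 1])
        assert manders(red, green) == (0.0, 0.0)

    def test_identical_binary_masks_give_one(self):
        m = np.array([[1, 0], [0, 1]])
        assert manders(m, m) == (1.0, 1.0)

    def test_zero_channel_sum_is_undefined(self):
        zero = np.zeros(4)
        m1, m2 = manders(zero, np.ones(4))
        assert np.isnan(m1) and m2 == 0.0

    def test_m1_non_increasing_in_green_threshold(self):
        rng = np.random.default_rng(1)
        red = rng.integers(0, 200, size=(10, 10))
        green = rng.integers(0, 200, size=(10, 10))
        m1s = [manders(red, green, t_green=t)[0] for t in range(0, 201, 10)]
        assert all(a >= b - 1e-15 for a, b in zip(m1s, m1s[1:]))

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            red = rng.integers(0, 50, size=(8, 8))
            green = rng.integers(0, 50, size=(8, 8))
            m1, m2 = manders(red, green, t_red=rng.integers(0, 50),
                             t_green=rng.integers(0, 50))
            for m in (m1, m2):
                if np.isfinite(m):
                    assert 0.0 <= m <= 1.0


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_pearson_and_manders_match_naive_loops(self, seed):
        rng = np.random.default_rng(seed)
        red = rng.integers(0, 256, size=(10, 10))
        green = rng.integers(0, 256, size=(10, 10))
        t_r, t_g = int(rng.integers(0, 256)), int(rng.integers(0, 256))
        assert pearson(red, green) == pytest.approx(
            pearson_naive(red.ravel().tolist(), green.ravel().tolist()), abs=1e-12)
        m1, m2 = manders(red, green, t_red=t_r, t_green=t_g)
        e1, e2 = manders_naive(red.ravel().tolist(), green.ravel().tolist(), t_r, t_g)
        assert m1 == pytest.approx(e1, abs=1e-12)
        assert m2 == pytest.approx(e2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_costes_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        # bright colocalized block over independent (uncorrelated) background
        red = rng.integers(0, 60, size=(10, 10))
        green = rng.integers(0, 60, size=(10, 10))
        red[3:7, 3:7] = rng.integers(150, 250, size=(4, 4))
        green[3:7, 3:7] = red[3:7, 3:7] + rng.integers(-20, 20, size=(4, 4))
        fit = costes_threshold(red, green)
        ref = costes_naive(red.ravel().tolist(), green.ravel().tolist())
        assert ref is not None
        a, b, t_red, t_green, rho = ref
        assert fit.slope == pytest.approx(a, abs=1e-9)
        assert fit.intercept == pytest.approx(b, abs=1e-9)
        if t_red is None:
            assert "scan_exhausted" in fit.flags
        else:
            assert fit.t_red == pytest.approx(t_red, abs=1e-9)
            assert fit.t_green == pytest.approx(t_green, abs=1e-9)


class TestCostes:
    def test_proportional_channels_threshold_at_bottom(self):
        rng = np.random.default_rng(0)
        red = rng.integers(1, 200, size=(12, 12))
        green = 2 * red
        # perfectly correlated pair: no sub-threshold population is ever
        # anti-correlated, so the scan runs to the bottom of the range
        fit = costes_threshold(red, green)
        assert fit.t_red <= red.min() + 3
        m1, m2 = manders(red, green, t_red=fit.t_red, t_green=fit.t_green)
        assert m1 == pytest.approx(1.0, abs=0.05)
        assert m2 == pytest.approx(1.0, abs=0.05)

    def test_stopping_contract_on_independent_noise(self):
        rng = np.random.default_rng(3)
        red = rng.integers(0, 255, size=(20, 20))
        green = rng.integers(0, 255, size=(20, 20))
        fit = costes_threshold(red, green)
        if "costes_not_applicable" in fit.flags:
            pytest.skip("anti-correlated draw; fallback path covered elsewhere")
        below = (red < fit.t_red) & (green < fit.t_green)
        assert pearson(red[below], green[below]) <= 0

    def test_contract_recheck_on_simulated_cells(self):
        field, mask, _ = simulate_field(make_params(**noisy_overrides(), seed=10))
        red, green = field.red.data, field.green.data
        for cid in mask.cell_ids():
            region = mask.labels == cid
            fit = costes_threshold(red, green, region)
            assert fit.flags == ()
            below = region & (red < fit.t_red) & (green < fit.t_green)
            assert pearson(red, green, below) <= 0
            # threshold pair lies on the fitted regression line
            assert fit.t_green == pytest.approx(
                fit.slope * fit.t_red + fit.intercept, abs=1e-9)

    def test_anticorrelated_channels_fall_back_with_flag(self):
        img = np.tile(np.arange(100), (2, 1)).reshape(20, 10)
        fit = costes_threshold(img, img.max() - img)
        assert "costes_not_applicable" in fit.flags
        assert fit.t_red > 0 and fit.t_green > 0  # Otsu fallback

    def test_needs_two_distinct_intensities(self):
        with pytest.raises(ValueError, match="distinct"):
            costes_threshold(np.full((4, 4), 5), np.arange(16).reshape(4, 4))


class TestColocPerCell:
    def test_noiseless_m1_equals_true_overlap_exactly(self):
        field, mask, truth = simulate_field(make_params(true_overlap=0.6))
        results = coloc_per_cell(field, mask, threshold_mode="none")
        for res, cell in zip(results, truth.cells):
            assert res.m1 == pytest.approx(cell.realized_overlap, abs=0)
            assert res.m1 == pytest.approx(0.6, abs=1e-12)
            assert res.m2 == pytest.approx(1.0, abs=1e-12)  # green lies on red

    def test_single_label_equals_whole_image_analysis(self):
        field, _, _ = simulate_field(make_params(**noisy_overrides()))
        whole = CellMask(labels=np.ones(field.shape, dtype=np.int32))
        res = coloc_per_cell(field, whole, threshold_mode="fixed",
                             t_red=100, t_green=100)[0]
        assert res.n_pixels == field.shape[0] * field.shape[1]
        assert res.pearson_r == pytest.approx(
            pearson(field.red.data, field.green.data), abs=1e-12)
        m1, m2 = manders(field.red.data, field.green.data,
                         t_red=100, t_green=100)
        assert (res.m1, res.m2) == (pytest.approx(m1), pytest.approx(m2))

    def test_overlap_recovery_under_noise_and_blur(self):
        errs = []
        for seed in range(20):
            params = make_params(**noisy_overrides(), seed=seed)
            field, mask, truth = simulate_field(params)
            for res, cell in zip(coloc_per_cell(field, mask), truth.cells):
                errs.append(res.m1 - cell.realized_overlap)
        assert np.mean(np.abs(errs)) <= 0.05

    def test_undefined_cells_flagged_without_aborting_others(self):
        red = np.zeros((20, 20), dtype=np.uint16)
        green = np.zeros((20, 20), dtype=np.uint16)
        red[2:6, 2:6] = 50
        green[2:6, 2:6] = 50
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[:10, :10] = 1   # has signal
        labels[10:, 10:] = 2   # constant zero in both channels
        field = field_from_arrays(red, green)
        results = coloc_per_cell(field, CellMask(labels=labels),
                                 threshold_mode="none")
        assert results[0].pearson_defined
        assert not results[1].pearson_defined
        assert any("undefined" in f for f in results[1].flags)

    def test_fixed_mode_requires_thresholds(self):
        field, mask, _ = simulate_field(make_params())
        with pytest.raises(ValueError, match="fixed"):
            coloc_per_cell(field, mask, threshold_mode="fixed")

    def test_mask_shape_mismatch_rejected(self):
        field, _, _ = simulate_field(make_params())
        bad = CellMask(labels=np.ones((8, 8), dtype=np.int32))
        with pytest.raises(ValueError, match="shape"):
            coloc_per_cell(field, bad)
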