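"""PSNR/SSIM (literal conventions), ROI restriction, ADC mapping."""

import math

import numpy as np
import pytest

from dwiguide import PhantomSpec, make_phantom, simulate_clean, simulate_repetitions
from dwiguide.metrics import (
    adc_map,
    dilate_mask,
    evaluate_series,
    psnr,
    roi_mean_adc,
    roi_metrics,
    ssim,
)
from dwiguide.pipeline import normalize_series


def naive_psnr(d, r, variant="literal"):
    d = np.asarray(d, np.float64).ravel()
    r = np.asarray(r, np.float64).ravel()
    mse = sum((a - b) ** 2 for a, b in zip(d, r)) / d.size
    peak = max(d)
    return 10 * math.log10((peak if variant == "literal" else peak**2) / mse)


def naive_global_ssim(d, r, eps=1e-12):
    d = np.asarray(d, np.float64).ravel()
    r = np.asarray(r, np.float64).ravel()
    mu_d, mu_r = d.mean(), r.mean()
    sd_d, sd_r = d.std(), r.std()
    cov = ((d - mu_d) * (r - mu_r)).mean()
    lum = 2 * mu_d * mu_r / (mu_d**2 + mu_r**2 + eps)
    con = 2 * sd_d * sd_r / (sd_d**2 + sd_r**2 + eps)
    return lum * con * (cov / (sd_d * sd_r + eps))


class TestPSNR:
    def test_twenty_db_case(self):
        # d_max = 1, MSE = 0.01 -> 10*log10(100) = 20
        r = np.zeros((10, 10))
        d = np.full((10, 10), 0.1)
        d[0, 0] = 1.0
        r[0, 0] = 1.1
        mse = np.mean((d - r) ** 2)
        assert mse == pytest.approx(0.01)
        assert psnr(d, r) == pytest.approx(10 * math.log10(1.0 / mse))

    def test_identical_images_signal_infinity(self, rng):
        d = rng.uniform(size=(5, 5))
        assert psnr(d, d.copy()) == float("inf")

    def test_paper_vs_standard_variant_offset(self, rng):
        # the two variants differ by 10*log10(d_max)
        d = rng.uniform(0.5, 2.0, size=(20, 20))
        r = d + rng.normal(0, 0.05, size=(20, 20))
        gap = psnr(d, r, variant="standard") - psnr(d, r, variant="literal")
        assert gap == pytest.approx(10 * math.log10(d.max()), rel=1e-9)

    def test_oracle_equivalence_on_random_pairs(self, rng):
        for _ in range(100):
            d = rng.uniform(0.1, 1.0, size=(8, 8))
            r = d + rng.normal(0, 0.1, size=(8, 8))
            for variant in ("literal", "standard"):
                assert psnr(d, r, variant=variant) == pytest.approx(
                    naive_psnr(d, r, variant), rel=1e-9
                )

    def test_decreases_with_noise_level(self, rng):
        r = rng.uniform(0.2, 1.0, size=(50, 50))
        values = []
        for sigma in (0.01, 0.05, 0.2):
            reps = [psnr(r + rng.normal(0, sigma, r.shape), r) for _ in range(20)]
            values.append(np.mean(reps))
        assert values[0] > values[1] > values[2]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSSIM:
    def test_identity_is_one(self, rng):
        d = rng.uniform(size=(10, 10))
        assert ssim(d, d.copy()) == pytest.approx(1.0, abs=1e-9)

    def test_constant_shift_closed_form(self, rng):
        # d = r + 0.5 with mu_r = 0.5: I = 2*0.5*1.0/(0.25+1.0) = 0.8, C = S = 1
        r = rng.normal(0, 0.05, size=(40, 40))
        r = r - r.mean() + 0.5
        d = r + 0.5
        assert ssim(d, r) == pytest.approx(0.8, abs=1e-9)

    def test_anticorrelation_gives_negative_value(self, rng):
        r = rng.uniform(0.2, 1.0, size=(20, 20))
        d = -r + 1.5
        assert ssim(d, r) < 0

    def test_symmetry(self, rng):
        d = rng.uniform(size=(12, 12))
        r = rng.uniform(size=(12, 12))
        assert ssim(d, r) == ssim(r, d)

    def test_degenerate_without_eps_raises(self):
        flat = np.full((5, 5), 0.3)
        with pytest.raises(ValueError):
            ssim(flat, flat + 0.1, eps=0)

    def test_oracle_equivalence_on_random_pairs(self, rng):
        for _ in range(100):
            d = rng.uniform(0.1, 1.0, size=(8, 8))
            r = d + rng.normal(0, 0.1, size=(8, 8))
            assert ssim(d, r) == pytest.approx(naive_global_ssim(d, r), rel=1e-9)

    def test_windowed_variant_close_to_one_for_identical(self, rng):
        d = rng.uniform(size=(16, 16))
        assert ssim(d, d.copy(), variant="windowed") == pytest.approx(1.0, abs=1e-7)


class TestROIMetrics:
    def test_full_mask_equals_global(self, rng):
        d = rng.uniform(size=(10, 10))
        r = rng.uniform(size=(10, 10))
        out = roi_metrics(d, r, np.ones_like(d, bool))
        assert out["psnr"] == psnr(d, r)
        assert out["ssim"] == ssim(d, r)

    def test_identical_inside_mask_infinite_roi_psnr(self, rng):
        r = rng.uniform(size=(10, 10))
        d = r.copy()
        d[0, :] += 1.0  # differ only outside the mask
        mask = np.zeros_like(d, bool)
        mask[5:8, 5:8] = True
        assert roi_metrics(d, r, mask)["psnr"] == float("inf")
        assert psnr(d, r) < float("inf")

    def test_invariant_to_pixels_outside_mask(self, rng):
        d = rng.uniform(size=(10, 10))
        r = rng.uniform(size=(10, 10))
        mask = np.zeros_like(d, bool)
        mask[2:6, 2:6] = True
        base = roi_metrics(d, r, mask)
        d2 = d.copy()
        d2[~mask] = 99.0
        assert roi_metrics(d2, r, mask) == base

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            roi_metrics(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_dilation_grows_mask(self):
        m = np.zeros((11, 11), bool)
        m[5, 5] = True
        assert dilate_mask(m, 3).sum() > 1


class TestADC:
    def test_equal_signals_give_zero(self):
        s = np.full((4, 4), 0.7)
        out = adc_map(s, s.copy(), 50, 800)
        assert np.all(out.adc[out.validity_mask] == 0)

    def test_scalar_inversion_case(self):
        # s_low = 1, s_high = exp(-0.75), db = 750 -> ADC = 1.000e-3 mm^2/s
        s_low = np.ones((2, 2))
        s_high = np.full((2, 2), math.exp(-0.75))
        out = adc_map(s_low, s_high, 50, 800)
        assert np.allclose(out.adc, 1.000e-3, rtol=1e-12)

    def test_invalid_pixels_masked_not_poisoning(self):
        s_low = np.array([[1.0, 0.0], [1.0, 1.0]])
        s_high = np.array([[0.5, 0.5], [0.0, 0.5]])
        out = adc_map(s_low, s_high, 0, 1000)
        assert not out.validity_mask[0, 1] and not out.validity_mask[1, 0]
        assert np.isfinite(out.adc[out.validity_mask]).all()

    def test_negative_adc_retained_and_flagged(self):
        out = adc_map(np.full((2, 2), 0.5), np.full((2, 2), 0.6), 50, 800)
        assert np.all(out.adc < 0)
        assert out.negative_mask.all()

    def test_nonpositive_delta_b_rejected(self):
        with pytest.raises(ValueError):
            adc_map(np.ones((2, 2)), np.ones((2, 2)), 800, 800)

    def test_roi_mean_uniform_region_exact(self):
        out = adc_map(np.ones((4, 4)), np.full((4, 4), math.exp(-1.5)), 0, 1000)
        assert roi_mean_adc(out, np.ones((4, 4), bool)) == pytest.approx(1.5e-3, rel=1e-12)

    def test_roi_mean_single_pixel(self):
        out = adc_map(np.ones((3, 3)), np.full((3, 3), 0.5), 0, 1000)
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert roi_mean_adc(out, mask) == pytest.approx(out.adc[1, 1])

    def test_roi_mean_excludes_invalid(self):
        s_low = np.ones((2, 2))
        s_low[0, 0] = 0.0
        out = adc_map(s_low, np.full((2, 2), 0.5), 0, 1000)
        val = roi_mean_adc(out, np.ones((2, 2), bool))
        assert val == pytest.approx(-math.log(0.5) / 1000)

    def test_roi_mean_empty_intersection_rejected(self):
        s_low = np.zeros((2, 2))
        s_low[0, 0] = 1.0
        out = adc_map(np.zeros((2, 2)), np.zeros((2, 2)) + 0.5, 0, 1000)
        with pytest.raises(ValueError):
            roi_mean_adc(out, np.ones((2, 2), bool))

    def test_per_pixel_adc_error_shrinks_with_nex(self):
        """Per-pixel ADC RMSE against ground truth falls as excitations are
        averaged (variance reduction; the small Rician floor bias remains)."""
        from dwiguide import PhantomSpec, make_dataset

        spec = PhantomSpec(n_slices=2, seed=31)
        pairs = make_dataset(spec, n_subjects=3, seed=31, nex_levels=(1, 4, 16))
        sq = {1: [], 4: [], 16: []}
        for series, gt in pairs:
            roi = gt.roi_mask
            for n in (1, 4, 16):
                amap = adc_map(series.guide, series.noisy[n], spec.b_low, spec.b_high)
                sel = roi & amap.validity_mask
                sq[n].append(np.mean((amap.adc[sel] - gt.adc_map[sel]) ** 2))
        rmse = {n: math.sqrt(np.mean(v)) for n, v in sq.items()}
        assert rmse[1] > rmse[4] > rmse[16]


class TestEvaluateSeries:
    def test_denoised_equal_reference_scores_perfectly(self, small_pairs):
        series, gt = small_pairs[0]
        s = normalize_series(series)
        den = {1: s.reference.copy()}
        report = evaluate_series(s, den, dilate_mask(gt.roi_mask, 3), nex_levels=(1,))
        d_rows = report.table[report.table.image == "denoised"]
        assert np.allclose(d_rows.ssim_global, 1.0, atol=1e-9)
        assert np.all(np.isinf(d_rows.psnr_global))

    def test_denoised_equal_noisy_gives_identical_columns(self, small_pairs):
        series, gt = small_pairs[0]
        s = normalize_series(series)
        den = {n: s.noisy[n].copy() for n in (1, 2)}
        report = evaluate_series(s, den, gt.roi_mask, nex_levels=(1, 2))
        piv = report.table.pivot_table(index=["nex", "slice"], columns="image", values="psnr_global")
        assert np.allclose(piv["denoised"], piv["noisy"])

    def test_row_count_enumeration(self, small_pairs):
        series, gt = small_pairs[0]
        s = normalize_series(series)
        den = {n: s.noisy[n] for n in (1, 2, 4)}
        report = evaluate_series(s, den, gt.roi_mask)
        assert len(report.table) == 3 * series.n_slices * 2  # NEX x slices x {noisy, denoised}
        assert len(report.adc) == 3 * 2 + 1  # + reference row
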