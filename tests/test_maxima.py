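import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from sheetquant.core_io import AnalysisConfig, Micrograph, Roi
from sheetquant.maxima import (
    FWHM_PER_SIGMA,
    Maximum,
    annotate_fwhm,
    detect_maxima,
    fit_fwhm,
    maxima_density,
)
from sheetquant.synthetic_data import SheetSimSpec, simulate_sheet

from conftest import gaussian_spot_image


def match_to_truth(detected_nm, true_nm, radius_nm):
    """Count one-to-one matches within a radius (Hungarian assignment)."""
    if len(detected_nm) == 0 or len(true_nm) == 0:
        return 0
    d = np.linalg.norm(detected_nm[:, None, :] - true_nm[None, :, :], axis=2)
    cost = np.where(d <= radius_nm, d, 1e9)
    ri, ci = linear_sum_assignment(cost)
    return int((cost[ri, ci] < 1e9).sum())


class TestDetection:
    def test_all_zero_image_yields_empty_set(self):
        mset = detect_maxima(Micrograph(np.zeros((64, 64)), 25.0))
        assert len(mset) == 0
        assert mset.density_per_um2 == 0.0

    def test_single_spot_subpixel_localization(self):
        img = gaussian_spot_image(center=(20.30, 41.70), amplitude=100, sigma_px=1.5)
        mset = detect_maxima(img)
        ok = [m for m in mset.maxima if m.excluded_reason is None]
        assert len(ok) == 1
        pos_px = np.array(ok[0].subpixel_pos_nm) / img.pixel_size_nm
        assert np.abs(pos_px - [20.30, 41.70]).max() < 0.1

    def test_intensity_is_disc_mean_on_raw_image(self):
        img = gaussian_spot_image(center=(32, 32), amplitude=100, sigma_px=1.5)
        mset = detect_maxima(img)
        (m,) = [m for m in mset.maxima if m.excluded_reason is None]
        # 13-px disc mean of the analytic spot
        vals = []
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                if dr * dr + dc * dc <= 4:
                    vals.append(img.pixels[32 + dr, 32 + dc])
        assert m.roi_mean_intensity_au == pytest.approx(np.mean(vals))

    def test_border_maxima_flagged_not_localized(self):
        img = gaussian_spot_image(center=(1.0, 32.0), amplitude=100, sigma_px=1.2)
        mset = detect_maxima(img)
        border = [m for m in mset.maxima if m.excluded_reason == "border"]
        assert border and all(m.subpixel_pos_nm is None for m in border)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(7)
        base = np.zeros((96, 96))
        for r, c in rng.uniform(20, 60, (5, 2)):
            rr = np.arange(96)[:, None]
            cc = np.arange(96)[None, :]
            base += 80 * np.exp(-(((rr - r) ** 2 + (cc - c) ** 2) / (2 * 1.5**2)))
        shifted = np.roll(np.roll(base, 7, axis=0), -5, axis=1)
        p0 = detect_maxima(Micrograph(base, 25.0)).positions_nm()
        p1 = detect_maxima(Micrograph(shifted, 25.0)).positions_nm()
        assert len(p0) == len(p1)
        expect = p0 + np.array([7 * 25.0, -5 * 25.0])
        order0 = np.lexsort((expect[:, 1], expect[:, 0]))
        order1 = np.lexsort((p1[:, 1], p1[:, 0]))
        np.testing.assert_allclose(p1[order1], expect[order0], atol=1e-6)

    def test_threshold_monotonicity(self):
        spec = SheetSimSpec(rng_seed=5)
        _, img_b, _ = simulate_sheet(spec)
        counts = [
            len(detect_maxima(img_b, cfg=AnalysisConfig(maxima_threshold_au=t)))
            for t in (1.0, 2.0, 5.0, 10.0, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_recall_precision_against_ground_truth(self):
        spec = SheetSimSpec(maxima_per_um2_B=3.0, assoc_fraction=0.0, rng_seed=11)
        _, img_b, truth = simulate_sheet(spec)
        mset = detect_maxima(img_b, spec.interior_roi())
        det = mset.positions_nm()
        n_match = match_to_truth(det, truth.positions_B_nm, spec.psf_fwhm_nm)
        recall = n_match / len(truth.positions_B_nm)
        precision = n_match / len(det)
        assert recall >= 0.9
        assert precision >= 0.9


class TestFwhm:
    def test_analytic_fwhm_recovered(self):
        sigma_nm = 40.0
        img = gaussian_spot_image(
            center=(32, 32), amplitude=100, sigma_px=sigma_nm / 25.0, background=5.0
        )
        mset = detect_maxima(img)
        (m,) = [m for m in mset.maxima if m.excluded_reason is None]
        fitted = fit_fwhm(img, m)
        expected = FWHM_PER_SIGMA * sigma_nm
        assert fitted.excluded_reason is None
        assert fitted.fwhm_nm == pytest.approx(expected, rel=0.02)
        assert fitted.fwhm_r2 >= 0.8

    def test_flat_profile_excluded(self):
        img = Micrograph(np.full((64, 64), 7.0), 25.0)
        m = Maximum((30, 30), (750.0, 750.0), 7.0)
        assert fit_fwhm(img, m).excluded_reason == "low_r2"

    def test_offcenter_peak_excluded(self):
        # spot 6 px away from the declared pixel maximum: fitted center lands
        # outside the middle third of the 15-px scan
        img = gaussian_spot_image(center=(30, 36), amplitude=100, sigma_px=1.5, background=1.0)
        m = Maximum((30, 30), (750.0, 750.0), 50.0)
        assert fit_fwhm(img, m).excluded_reason == "noncentered"

    def test_scan_outside_image_flagged_border(self):
        img = gaussian_spot_image(center=(3, 32), amplitude=100, sigma_px=1.5)
        m = Maximum((3, 32), (75.0, 800.0), 50.0)
        assert fit_fwhm(img, m).excluded_reason == "border"

    def test_annotate_fwhm_runs_over_set(self):
        img = gaussian_spot_image(center=(32, 32), amplitude=100, sigma_px=1.6)
        mset = annotate_fwhm(img, detect_maxima(img))
        assert any(m.fwhm_nm is not None for m in mset.maxima)


class TestDensity:
    def test_density_arithmetic(self):
        # 100 maxima in a 400x400 px ROI at 25 nm/px = 100 um^2 -> 1.0 per um^2
        roi = Roi(rect=(0, 0, 400, 400))
        maxima = tuple(
            Maximum((i, i), (i * 25.0, i * 25.0), 10.0) for i in range(2, 102)
        )
        from sheetquant.maxima import MaximaSet

        mset = MaximaSet(maxima, roi, 25.0, density_per_um2=0.0)
        assert maxima_density(mset) == pytest.approx(1.0)

    def test_empty_set_density_zero(self):
        mset = detect_maxima(Micrograph(np.zeros((64, 64)), 25.0))
        assert maxima_density(mset) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_simulated_density_recovered(self, seed):
        spec = SheetSimSpec(
            maxima_per_um2_B=2.2, clusters_per_um2_A=0.0, assoc_fraction=0.0, rng_seed=seed
        )
        _, img_b, truth = simulate_sheet(spec)
        mset = detect_maxima(img_b, spec.interior_roi())
        true_density = len(truth.positions_B_nm) / spec.interior_area_um2
        assert mset.density_per_um2 == pytest.approx(true_density, rel=0.15)
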