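import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheetquant.coloc import (
    corrected_mean,
    normalize_to_reference,
    pearson,
    roi_stats,
    rsdm,
)
from sheetquant.core_io import Micrograph, Roi
from sheetquant.synthetic_data import (
    AggregationSpec,
    SheetSimSpec,
    simulate_crosslink,
    simulate_sheet,
)

ROI = Roi(rect=(0, 0, 32, 32))


def img_of(arr, px=25.0):
    return Micrograph(np.asarray(arr, dtype=float), px)


class TestCorrectedMean:
    def test_arithmetic(self):
        arr = np.zeros((32, 32))
        arr[:16, :] = 110.0
        arr[16:, :] = 10.0
        img = img_of(arr)
        val = corrected_mean(img, Roi(rect=(0, 0, 16, 32)), Roi(rect=(16, 0, 16, 32)))
        assert val == pytest.approx(100.0)

    def test_overlapping_rois_rejected(self):
        img = img_of(np.ones((32, 32)))
        with pytest.raises(ValueError):
            corrected_mean(img, ROI, ROI)

    def test_equal_level_rois_give_zero(self):
        img = img_of(np.full((32, 32), 7.0))
        val = corrected_mean(img, Roi(rect=(0, 0, 16, 32)), Roi(rect=(16, 0, 16, 32)))
        assert val == 0.0

    def test_simulated_background_only_field(self):
        spec = SheetSimSpec(
            clusters_per_um2_A=0.0,
            maxima_per_um2_B=0.0,
            background_au=10.0,
            noise_model=("gaussian", 1.0),
            rng_seed=1,
        )
        img_a, _, _ = simulate_sheet(spec)
        # signal-free: membrane-minus-background corrected mean centered on 0
        val = corrected_mean(
            img_a, Roi(rect=(0, 0, 128, 256)), Roi(rect=(128, 0, 128, 256))
        )
        sd_of_mean = 1.0 / np.sqrt(128 * 256)
        assert abs(val) < 5 * np.sqrt(2) * sd_of_mean


class TestPearson:
    def test_identical_channels(self):
        rng = np.random.default_rng(0)
        a = img_of(rng.uniform(1, 100, (32, 32)))
        assert pearson(a, a, ROI) == pytest.approx(1.0)

    def test_negated_channels(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(1, 100, (32, 32))
        a = img_of(arr)
        b = img_of(200.0 - arr)
        assert pearson(a, b, ROI) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = img_of(np.ones((32, 32)))
        b = img_of(np.random.default_rng(0).uniform(0, 1, (32, 32)))
        with pytest.raises(ValueError):
            pearson(a, b, ROI)

    def test_independent_noise_near_zero(self):
        hits = 0
        n_px = 100 * 100
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = img_of(rng.uniform(0, 100, (100, 100)))
            b = img_of(rng.uniform(0, 100, (100, 100)))
            if abs(pearson(a, b, Roi(rect=(0, 0, 100, 100)))) < 0.05:
                hits += 1
        # null SD of r is ~1/sqrt(n) = 0.01; 0.05 is 5 sigma
        assert hits >= 19

    @given(gain=st.floats(0.1, 10.0), offset=st.floats(0.0, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(12)
        arr = rng.uniform(1, 100, (32, 32))
        other = rng.uniform(1, 100, (32, 32))
        r0 = pearson(img_of(arr), img_of(other), ROI)
        r1 = pearson(img_of(gain * arr + offset), img_of(other), ROI)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestRsdm:
    def test_uniform_roi_is_zero(self):
        assert rsdm(img_of(np.full((32, 32), 5.0)), ROI) == 0.0

    def test_balanced_binary_is_one(self):
        arr = np.zeros((32, 32))
        arr[:16] = 1.0
        assert rsdm(img_of(arr), ROI) == pytest.approx(1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            rsdm(img_of(np.zeros((32, 32))), ROI)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_multiplicative_invariance(self, scale):
        rng = np.random.default_rng(3)
        arr = rng.uniform(1, 10, (32, 32))
        assert rsdm(img_of(scale * arr), ROI) == pytest.approx(rsdm(img_of(arr), ROI))

    @pytest.mark.parametrize("seed", range(5))
    def test_aggregation_increases_rsdm(self, seed):
        spec = SheetSimSpec(
            rng_seed=seed, aggregation=AggregationSpec(n_aggregates=11, co_drag_fraction=0.0)
        )
        img_a, _, truth = simulate_sheet(spec)
        agg_a, _, _ = simulate_crosslink(spec, truth)
        roi = spec.interior_roi()
        assert rsdm(agg_a, roi) > rsdm(img_a, roi)


class TestNormalization:
    def test_reference_maps_to_100(self):
        df = pd.DataFrame(
            {"condition": ["fixed"] * 3 + ["CoP"] * 3, "value": [2.0, 2.0, 2.0, 4.0, 4.0, 4.0]}
        )
        out = normalize_to_reference(df, "fixed", experiment_col=None)
        fixed = out[out.condition == "fixed"].iloc[0]
        cop = out[out.condition == "CoP"].iloc[0]
        assert fixed.mean_percent == pytest.approx(100.0)
        assert cop.mean_percent == pytest.approx(200.0)

    def test_hand_computed_sd(self):
        df = pd.DataFrame(
            {
                "condition": ["fixed", "fixed", "CoP", "CoP", "CoP"],
                "value": [1.0, 3.0, 2.0, 4.0, 6.0],
            }
        )
        out = normalize_to_reference(df, "fixed", experiment_col=None)
        cop = out[out.condition == "CoP"].iloc[0]
        # reference mean 2 -> percents 100, 200, 300
        assert cop.mean_percent == pytest.approx(200.0)
        assert cop.sd_percent == pytest.approx(100.0)

    def test_experiment_hierarchy(self):
        # sheets average per experiment first, SD across experiments
        df = pd.DataFrame(
            {
                "condition": ["fixed"] * 4 + ["CoP"] * 4,
                "experiment": [1, 1, 2, 2] * 2,
                "value": [1.0, 3.0, 2.0, 2.0, 2.0, 6.0, 4.0, 4.0],
            }
        )
        out = normalize_to_reference(df, "fixed")
        cop = out[out.condition == "CoP"].iloc[0]
        assert cop.n == 2  # two experiments, not four sheets
        assert cop.mean_percent == pytest.approx(200.0)

    def test_missing_reference_rejected(self):
        df = pd.DataFrame({"condition": ["a"], "value": [1.0]})
        with pytest.raises(ValueError):
            normalize_to_reference(df, "fixed", experiment_col=None)


def test_roi_stats_reports_missing_reason():
    a = img_of(np.ones((32, 32)))
    b = img_of(np.ones((32, 32)))
    stats = roi_stats(a, b, ROI)
    assert stats.pcc is None
    assert "variance" in stats.missing_reason
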