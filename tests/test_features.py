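"""Colour histograms, LBP texture codes and feature assembly."""

import numpy as np
import pytest

from steatolens.cases import DonorRecord
from steatolens.features import (
    ClinicalScaler,
    FeatureConfig,
    FeatureError,
    build_features,
    feature_names,
    lab_histogram,
    lbp_codes,
    lbp_histogram,
    patch_image_features,
)
from steatolens.patching import Patch


def brute_force_lbp(x):
    """Independent per-pixel oracle for the 8-neighbour LBP."""
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    h, w = x.shape
    out = np.zeros((h - 2, w - 2), dtype=int)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for i, (dr, dc) in enumerate(offsets):
                if x[r + dr, c + dc] >= x[r, c]:
                    code |= 1 << i
            out[r - 1, c - 1] = code
    return out


class TestLabHistogram:
    def test_constant_channel_single_bin(self):
        h = lab_histogram(np.full(50, 55.0), (0, 100), 32)
        assert h.sum() == pytest.approx(1.0)
        assert h.max() == pytest.approx(1.0)

    def test_two_values_split_mass(self):
        h = lab_histogram(np.array([10.0, 10.0, 90.0, 90.0]), (0, 100), 10)
        assert h[1] == pytest.approx(0.5) and h[9] == pytest.approx(0.5)

    def test_out_of_range_clipped_to_edge_bins(self):
        h = lab_histogram(np.array([-500.0, 500.0]), (-128, 127), 32)
        assert h[0] == pytest.approx(0.5) and h[-1] == pytest.approx(0.5)

    def test_permutation_invariance(self, rng):
        vals = rng.uniform(0, 100, 200)
        h1 = lab_histogram(vals, (0, 100), 32)
        h2 = lab_histogram(rng.permutation(vals), (0, 100), 32)
        assert np.allclose(h1, h2)

    def test_empty_errors(self):
        with pytest.raises(FeatureError):
            lab_histogram(np.array([]), (0, 100), 32)


class TestLbp:
    def test_constant_patch_codes_255(self):
        assert (lbp_codes(np.full((6, 6), 3.0)) == 255).all()

    def test_strict_maximum_codes_0(self):
        x = np.zeros((5, 5))
        x[2, 2] = 10.0
        assert lbp_codes(x)[1, 1] == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            x = rng.random((8, 8))
            assert np.array_equal(lbp_codes(x), brute_force_lbp(x))

    def test_checkerboard_concentrates_on_two_codes(self):
        x = np.indices((8, 8)).sum(axis=0) % 2 * 5.0
        h = lbp_histogram(lbp_codes(x))
        # high centres see >= at the 4 corners (bits 0,2,4,6 -> 85);
        # low centres see >= everywhere (255)
        assert h[85] + h[255] == pytest.approx(1.0)

    def test_invariant_to_additive_shift(self, rng):
        x = rng.random((10, 10))
        assert np.array_equal(lbp_codes(x), lbp_codes(x + 17.3))

    def test_small_grid_errors(self):
        with pytest.raises(FeatureError):
            lbp_codes(np.zeros((2, 5)))


def _patch_from(lab):
    return Patch(row=0, col=0, side=lab.shape[0], lab=lab, mean_L=float(lab[..., 0].mean()))


class TestBuildFeatures:
    def test_image_only_length(self, rng):
        patch = _patch_from(rng.uniform(0, 50, (16, 16, 3)))
        vec = build_features(patch, FeatureConfig()).vector
        assert vec.shape == (3 * 32 + 3 * 256,) == (864,)

    def test_with_clinical_length(self, rng):
        donors = [
            DonorRecord(f"D{i}", age=50 + i, sex="M" if i % 2 else "F", bmi=25 + i,
                        ast=30 + i, alt=28 + i, ggt=40 + i, bilirubin=0.5)
            for i in range(5)
        ]
        scaler = ClinicalScaler.fit(donors)
        patch = _patch_from(rng.uniform(0, 50, (16, 16, 3)))
        cfg = FeatureConfig(use_clinical=True)
        vec = build_features(patch, cfg, donor=donors[0], scaler=scaler).vector
        assert vec.shape == (871,)
        assert len(feature_names(cfg)) == 871

    def test_clinical_requested_but_absent_errors(self, rng):
        patch = _patch_from(rng.uniform(0, 50, (16, 16, 3)))
        with pytest.raises(FeatureError):
            build_features(patch, FeatureConfig(use_clinical=True))

    def test_median_donor_maps_to_zero_block(self):
        donors = [
            DonorRecord(f"D{i}", age=a, sex="M", bmi=b, ast=30, alt=25, ggt=40, bilirubin=0.5)
            for i, (a, b) in enumerate([(40, 22), (50, 26), (60, 30)])
        ]
        scaler = ClinicalScaler.fit(donors)
        median_donor = DonorRecord("Dm", age=50, sex="M", bmi=26, ast=30, alt=25,
                                   ggt=40, bilirubin=0.5)
        assert np.allclose(scaler.transform(median_donor), 0.0)

    def test_missing_values_imputed_to_zero(self):
        donors = [
            DonorRecord(f"D{i}", age=40 + 10 * i, sex="F", bmi=24 + i, ast=30,
                        alt=25, ggt=40, bilirubin=0.5)
            for i in range(4)
        ]
        scaler = ClinicalScaler.fit(donors)
        sparse = DonorRecord("Dx")  # everything missing
        assert np.allclose(scaler.transform(sparse), 0.0)

    def test_histograms_sum_to_one(self, rng):
        pf = patch_image_features(_patch_from(rng.uniform(-20, 80, (12, 12, 3))), FeatureConfig())
        assert np.allclose(pf.colour_hist.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(pf.lbp_hist.sum(axis=1), 1.0, atol=1e-9)


class TestCalibrationInvariance:
    def test_features_invariant_to_corrected_gain_distortion(self, rng):
        """Calibrating a channel-gain-distorted image recovers the features."""
        from steatolens.imaging import (
            estimate_card_colour,
            rgb_to_lab,
            srgb_decode,
            srgb_encode,
            white_balance,
        )

        base = rng.uniform(0.05, 0.45, (64, 64, 3))
        base[:8, :8] = 0.18  # neutral card
        gains = np.array([1.15, 0.85, 1.05])
        distorted_png = srgb_encode(np.clip(base * gains, 0, 1))

        def features_of(linear):
            lab = rgb_to_lab(linear)
            patch = Patch(row=20, col=20, side=32, lab=lab[20:52, 20:52],
                          mean_L=0.0)
            return patch_image_features(patch, FeatureConfig()).vector

        linear = srgb_decode(distorted_png)
        card = estimate_card_colour(linear, (0, 0, 8, 8))
        calibrated, _ = white_balance(linear, card)

        reference, _ = white_balance(
            base, estimate_card_colour(base, (0, 0, 8, 8))
        )
        assert np.abs(features_of(calibrated) - features_of(reference)).max() < 1e-3
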