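"""Detection scores, skill scores, calibration, overlap, integrated probability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p3nmr.metrics import (EvalConfig, detection_threshold, detectable_pixels,
                           detection_scores, brier_and_bce, calibration_curve,
                           overlap_score, integrated_probability)
from p3nmr.spectra import (AcqGrid, ParamRanges, sample_spectrum_params,
                           simulate_fid, process_spectrum, make_label_mask)
from p3nmr.seeding import substream


class TestDetectability:
    def test_threshold_triple(self):
        # the 2 sigma US threshold scales to ~5 sigma at 15% and ~9 at 5%
        assert detection_threshold(EvalConfig(nus_fraction=1.0)) == pytest.approx(2.0)
        assert detection_threshold(EvalConfig(nus_fraction=0.15)) == pytest.approx(5.0, abs=0.2)
        assert detection_threshold(EvalConfig(nus_fraction=0.05)) == pytest.approx(9.0, abs=0.1)

    def test_strict_inequality_at_threshold(self):
        grid = AcqGrid((32, 128))
        rng = substream(1, "d")
        p = sample_spectrum_params(ParamRanges(amp_sigma=(2.0, 2.0)), 5, rng, grid=grid)
        s = process_spectrum(simulate_fid(p, grid), grid)
        s.sigma_noise = 1.0
        det = detectable_pixels(p, s, EvalConfig())
        assert not det.any()  # exactly at 2 sigma: excluded

    def test_above_threshold_detectable(self):
        grid = AcqGrid((32, 128))
        rng = substream(2, "d")
        p = sample_spectrum_params(ParamRanges(amp_sigma=(10.0, 10.0)), 5, rng, grid=grid)
        s = process_spectrum(simulate_fid(p, grid), grid)
        det = detectable_pixels(p, s, EvalConfig())
        m = make_label_mask(p, s)
        assert np.array_equal(det, m.data.astype(bool))


class TestDetectionScores:
    def test_perfect(self):
        truth = np.zeros((20, 20), dtype=bool)
        truth[5, 5] = truth[12, 15] = True
        p3 = truth.astype(float)
        s = detection_scores(p3, truth, EvalConfig(probability_threshold=0.5))
        assert (s["recall"], s["precision"], s["f1"]) == (1.0, 1.0, 1.0)

    def test_f1_harmonic_mean(self):
        assert 2 * 1.0 * (1 / 3) / (1.0 + 1 / 3) == pytest.approx(0.5)
        truth = np.zeros((40, 40), dtype=bool)
        truth[(5, 15, 25), (5, 15, 25)] = True
        p3 = np.zeros((40, 40))
        p3[5, 5] = 1.0  # one of three found, nothing spurious
        s = detection_scores(p3, truth, EvalConfig(probability_threshold=0.5))
        assert s["precision"] == 1.0
        assert s["recall"] == pytest.approx(1 / 3)
        assert s["f1"] == pytest.approx(0.5)

    def test_vicinity_matching(self):
        truth = np.zeros((20, 20), dtype=bool)
        truth[10, 10] = True
        p3 = np.zeros((20, 20))
        p3[10, 12] = 1.0  # 2 pixels away: inside the default vicinity
        s = detection_scores(p3, truth, EvalConfig())
        assert s["precision"] == 1.0 and s["recall"] == 1.0
        s2 = detection_scores(p3, truth, EvalConfig(vicinity_radius=1.0))
        assert s2["precision"] == 0.0 and s2["recall"] == 0.0

    def test_zero_denominators_flagged(self):
        s = detection_scores(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool),
                             EvalConfig())
        assert s["f1"] == 0.0
        assert len(s["flags"]) == 2


class TestSkillScores:
    def test_reference_values(self):
        y = np.concatenate([np.ones(500), np.zeros(500)])
        r = brier_and_bce(np.full(1000, 0.5), y)
        assert r["pi"] == 0.5
        assert r["brier_ref"] == pytest.approx(0.25)

    def test_perfect_predictor(self):
        y = np.concatenate([np.ones(10), np.zeros(90)])
        r = brier_and_bce(y.astype(float), y)
        assert r["brier"] == 0.0 and r["bce"] == 0.0
        assert r["bss"] == 1.0 and r["bce_ss"] == 1.0

    def test_base_rate_predictor_zero_skill(self):
        y = np.concatenate([np.ones(30), np.zeros(970)])
        pi = y.mean()
        r = brier_and_bce(np.full_like(y, pi, dtype=float), y)
        assert r["brier"] == pytest.approx(r["brier_ref"])
        assert r["bss"] == pytest.approx(0.0, abs=1e-12)
        assert r["bce_ss"] == pytest.approx(0.0, abs=1e-12)

    def test_single_class_flagged(self):
        r = brier_and_bce(np.full(10, 0.9), np.ones(10))
        assert np.isnan(r["bss"])
        assert r["flags"]

    def test_bounds(self):
        rng = substream(3, "sk")
        p = rng.uniform(size=1000)
        y = (rng.uniform(size=1000) < 0.3).astype(float)
        r = brier_and_bce(p, y)
        assert 0 <= r["brier"] <= 1
        assert r["bce"] >= 0
        assert r["bss"] <= 1 and r["bce_ss"] <= 1

    def test_invariant_under_permutation(self):
        rng = substream(4, "sk")
        p = rng.uniform(size=500)
        y = (rng.uniform(size=500) < p).astype(float)
        perm = rng.permutation(500)
        a = brier_and_bce(p, y)
        b = brier_and_bce(p[perm], y[perm])
        assert a["brier"] == pytest.approx(b["brier"])
        assert a["bce"] == pytest.approx(b["bce"])


class TestCalibrationCurve:
    def test_well_calibrated_draws(self):
        rng = substream(5, "cal")
        p = rng.uniform(size=100_000)
        y = (rng.uniform(size=len(p)) < p).astype(float)
        for row in calibration_curve(p, y):
            n = row["count"]
            se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / n)
            assert abs(row["observed_fraction"] - row["mean_predicted"]) <= 4 * se + 0.01

    def test_all_ones(self):
        rows = calibration_curve(np.ones(50), np.ones(50))
        assert len(rows) == 1
        assert rows[0]["mean_predicted"] == 1.0
        assert rows[0]["observed_fraction"] == 1.0

    def test_empty_bins_absent(self):
        rows = calibration_curve(np.full(100, 0.55), np.zeros(100))
        assert len(rows) == 1
        assert rows[0]["bin"] == pytest.approx((0.5, 0.6))


class TestOverlapScore:
    def test_isolated_zero(self):
        s, flags = overlap_score(0, [[5.0, 5.0]], [1.0])
        assert s == 0.0 and not flags

    def test_single_neighbor(self):
        s, _ = overlap_score(0, [[0, 0], [0, 4.0]], [2.0, 2.0])
        assert s == pytest.approx(1 / 16)

    def test_two_equal_neighbors_additive(self):
        s1, _ = overlap_score(0, [[0, 0], [4.0, 0]], [1.0, 1.0])
        s2, _ = overlap_score(0, [[0, 0], [4.0, 0], [0, 4.0]], [1.0, 1.0, 1.0])
        assert s2 == pytest.approx(2 * s1)

    def test_radius_cut(self):
        s, _ = overlap_score(0, [[0, 0], [0, 16.0]], [1.0, 1.0])
        assert s == 0.0

    def test_coincident_flagged(self):
        s, flags = overlap_score(0, [[0, 0], [0, 0]], [1.0, 1.0])
        assert s == 0.0 and flags


class TestIntegratedProbability:
    def test_zeros(self):
        assert integrated_probability(np.zeros((5, 5)), np.ones((5, 5), bool)) == 0.0

    def test_single_labeled_pixel(self):
        p = np.zeros((5, 5))
        p[2, 2] = 1.0
        assert integrated_probability(p, np.ones((5, 5), bool)) == 1.0

    def test_region_additivity(self):
        rng = substream(6, "ip")
        p = rng.uniform(size=(10, 10))
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:5] = True
        b[5:] = True
        assert integrated_probability(p, a | b) == pytest.approx(
            integrated_probability(p, a) + integrated_probability(p, b))
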