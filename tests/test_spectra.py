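"""Simulation, processing, labeling and parameter sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p3nmr.spectra import (AcqGrid, SignalParams, ParamRanges, simulate_fid,
                           process_spectrum, make_label_mask, skyline_project,
                           sample_spectrum_params, peak_positions, noise_gain,
                           peak_height_factor)
from p3nmr.seeding import substream


def single(omega, tau, phase=0.0, amp=1.0, n=2):
    return SignalParams(np.array([amp]), np.full((1, n), float(omega)) if np.isscalar(omega) else np.array([omega]),
                        np.full((1, n), float(tau)) if np.isscalar(tau) else np.array([tau]),
                        np.full((1, n), float(phase)))


GRID = AcqGrid((32, 128))


class TestSimulateFid:
    def test_nondecaying_on_resonance(self):
        fid = simulate_fid(single(0.0, 1e9), GRID)
        assert np.allclose(fid[0, 0], 1.0, atol=1e-6)
        assert np.allclose(fid[0, 1], 0.0)
        assert np.allclose(fid[1, 0], 0.0)
        assert np.allclose(fid[1, 1], 0.0)

    def test_zero_peaks(self):
        fid = simulate_fid(SignalParams.empty(2), GRID)
        assert fid.shape == (2, 2, 32, 128)
        assert np.all(fid == 0)

    def test_two_peaks_sum_at_t0(self):
        p = SignalParams(np.array([1.5, 2.5]), np.array([[0.1, 0.2], [-0.3, 0.05]]),
                         np.full((2, 2), 20.0), np.zeros((2, 2)))
        fid = simulate_fid(p, GRID)
        assert fid[0, 0, 0, 0] == pytest.approx(4.0)

    def test_linearity(self):
        rng = substream(7, "lin")
        r = ParamRanges()
        a = sample_spectrum_params(r, 3, rng, n_dims=2)
        b = sample_spectrum_params(r, 4, rng, n_dims=2)
        both = SignalParams(np.concatenate([a.amplitude, b.amplitude]),
                            np.concatenate([a.omega, b.omega]),
                            np.concatenate([a.tau, b.tau]),
                            np.concatenate([a.phase_deg, b.phase_deg]))
        sa = process_spectrum(simulate_fid(a, GRID), GRID).data
        sb = process_spectrum(simulate_fid(b, GRID), GRID).data
        sab = process_spectrum(simulate_fid(both, GRID), GRID).data
        assert np.allclose(sab, sa + sb, atol=1e-9 * np.abs(sab).max())

    @pytest.mark.parametrize("bad", [
        dict(omega=0.6, tau=10.0),   # outside Nyquist
        dict(omega=0.1, tau=-1.0),   # negative relaxation
        dict(omega=0.1, tau=10.0, amp=-2.0),  # negative amplitude
    ])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            simulate_fid(single(**bad), GRID)


class TestProcessSpectrum:
    def test_peak_at_expected_index(self):
        spec = process_spectrum(simulate_fid(single([0.25, -0.1], 30.0), GRID), GRID)
        idx = np.unravel_index(np.argmax(spec.data), spec.data.shape)
        expect = (64 * (0.25 + 0.5), 256 * (-0.1 + 0.5))
        assert abs(idx[0] - expect[0]) <= 1
        assert abs(idx[1] - expect[1]) <= 1

    def test_all_zero_input(self):
        spec = process_spectrum(np.zeros((2, 2, 32, 128)), GRID)
        assert np.all(spec.data == 0)

    def test_nondecaying_fwhm_at_most_3(self):
        # the sharpest line the discrete FT can produce spans 2-3 points
        spec = process_spectrum(simulate_fid(single(0.0, 1e9), GRID), GRID)
        for axis in (0, 1):
            i = np.unravel_index(np.argmax(spec.data), spec.data.shape)
            line = spec.data[i[0], :] if axis == 1 else spec.data[:, i[1]]
            j = int(np.argmax(line))
            h = line[j] / 2
            lo = j
            while line[lo] > h:
                lo -= 1
            hi = j
            while line[hi] > h:
                hi += 1
            xl = lo + (h - line[lo]) / (line[lo + 1] - line[lo])
            xr = hi - 1 + (line[hi - 1] - h) / (line[hi - 1] - line[hi])
            assert xr - xl <= 3.0

    def test_rejects_small_zero_fill(self):
        with pytest.raises(ValueError):
            AcqGrid((32, 128), zero_fill=1)

    def test_quadrature_shape(self):
        spec = process_spectrum(simulate_fid(single(0.1, 20.0), GRID), GRID)
        assert spec.quad.shape == (2, 2, 64, 256)
        assert np.array_equal(spec.quad[0, 0], spec.data)


class TestLabelMask:
    def grid_spectrum(self, omega):
        p = single(omega, 25.0)
        return p, process_spectrum(simulate_fid(p, GRID), GRID)

    def test_dual_label_at_half(self):
        # fractional position 0.5 between indices labels both
        om = (10.5 / 64 - 0.5, 0.0)
        p, s = self.grid_spectrum(om)
        m = make_label_mask(p, s)
        rows = np.argwhere(m.data)[:, 0]
        assert set(rows) == {10, 11}

    def test_exact_index_single_label(self):
        om = (10.0 / 64 - 0.5, 0.0)
        p, s = self.grid_spectrum(om)
        m = make_label_mask(p, s)
        assert set(np.argwhere(m.data)[:, 0]) == {10}

    def test_outside_dual_band_single_label(self):
        # 10.8 is 0.2 away from index 11: outside the 0.25-0.75 band
        om = (10.8 / 64 - 0.5, 0.0)
        p, s = self.grid_spectrum(om)
        m = make_label_mask(p, s)
        assert set(np.argwhere(m.data)[:, 0]) == {11}

    def test_label_matches_argmax_high_snr(self):
        # for isolated noise-free peaks the labeled set contains the argmax
        rng = substream(11, "labels")
        hits = 0
        n = 200
        for _ in range(n):
            p = sample_spectrum_params(ParamRanges(), 1, rng, grid=GRID)
            s = process_spectrum(simulate_fid(p, GRID), GRID)
            m = make_label_mask(p, s)
            idx = np.unravel_index(np.argmax(np.abs(s.data)), s.data.shape)
            if m.data[idx] == 1:
                hits += 1
        assert hits / n >= 0.99

    def test_count_at_least_n_peaks(self):
        rng = substream(12, "labels2")
        p = sample_spectrum_params(ParamRanges(), 64, rng, grid=GRID)
        s = process_spectrum(simulate_fid(p, GRID), GRID)
        m = make_label_mask(p, s)
        # dual labeling can only add points (overlaps can merge a few)
        assert m.n_positive >= 0.9 * 64


class TestSkyline:
    def make3d(self, params):
        g = AcqGrid((8, 8, 16))
        return process_spectrum(simulate_fid(params, g), g)

    def test_all_zero(self):
        s = self.make3d(SignalParams.empty(3))
        p = skyline_project(s, 0)
        assert p.data.shape == (16, 32)
        assert np.all(p.data == 0)

    def test_single_peak_max_invariant(self):
        p = SignalParams(np.array([2.0]), np.array([[0.1, -0.2, 0.3]]),
                         np.full((1, 3), 10.0), np.zeros((1, 3)))
        s = self.make3d(p)
        for axis in range(3):
            assert skyline_project(s, axis).data.max() == pytest.approx(s.data.max())

    def test_two_peaks_merge_to_larger(self):
        p = SignalParams(np.array([1.0, 3.0]), np.array([[0.1, -0.2, 0.3],
                                                         [0.1, -0.2, -0.25]]),
                         np.full((2, 3), 30.0), np.zeros((2, 3)))
        s = self.make3d(p)
        proj = skyline_project(s, 2)  # drop the axis separating the peaks
        i = np.unravel_index(np.argmax(proj.data), proj.data.shape)
        assert proj.data[i] == pytest.approx(s.data.max())

    def test_scaling_commutes(self):
        p = SignalParams(np.array([1.0]), np.array([[0.1, -0.2, 0.3]]),
                         np.full((1, 3), 10.0), np.zeros((1, 3)))
        s = self.make3d(p)
        import dataclasses
        s2 = dataclasses.replace(s, data=3.5 * s.data)
        assert np.allclose(skyline_project(s2, 1).data,
                           3.5 * skyline_project(s, 1).data)

    def test_invalid_axis(self):
        s = self.make3d(SignalParams.empty(3))
        with pytest.raises(ValueError):
            skyline_project(s, 3)


class TestSampling:
    def test_dynamic_range_and_floor(self):
        rng = substream(3, "s")
        p = sample_spectrum_params(ParamRanges(), 256, rng, grid=GRID)
        assert p.amp_sigma.min() >= 1.0
        assert p.amp_sigma.max() / p.amp_sigma.min() <= 200.0

    def test_determinism(self):
        a = sample_spectrum_params(ParamRanges(), 50, substream(5, "x"), n_dims=2)
        b = sample_spectrum_params(ParamRanges(), 50, substream(5, "x"), n_dims=2)
        assert np.array_equal(a.omega, b.omega)
        assert np.array_equal(a.amplitude, b.amplitude)

    def test_phase_band(self):
        p = sample_spectrum_params(ParamRanges(phase_deg=5.0), 500,
                                   substream(6, "y"), n_dims=2)
        assert np.all(np.abs(p.phase_deg) <= 5.0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            ParamRanges(amp_sigma=(5.0, 1.0)).validate()

    def test_sigma_unit_calibration(self):
        # a peak of amplitude A sigma-units should rise A*sigma_f above zero
        rng = substream(8, "cal")
        p = sample_spectrum_params(ParamRanges(amp_sigma=(50.0, 50.0)), 1, rng,
                                   grid=GRID)
        fine = AcqGrid(GRID.t_points, zero_fill=8)
        s = process_spectrum(simulate_fid(p, fine), fine)
        assert s.data.max() / noise_gain(GRID) == pytest.approx(50.0, rel=0.02)


@settings(max_examples=20, deadline=None)
@given(st.floats(min_value=-0.45, max_value=0.45),
       st.floats(min_value=8.0, max_value=128.0))
def test_peak_position_formula(omega, tau):
    """The processed peak maximum lies within a pixel of N (w + 0.5)."""
    p = single([omega, 0.0], [tau, 30.0])
    s = process_spectrum(simulate_fid(p, GRID), GRID)
    idx = np.unravel_index(np.argmax(s.data), s.data.shape)
    assert abs(idx[0] - 64 * (omega + 0.5)) <= 1.0
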