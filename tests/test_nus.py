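"""Schedules, subsampling, CS-IST reconstruction, time-domain regeneration."""

import numpy as np
import pytest

from p3nmr.spectra import (AcqGrid, SignalParams, simulate_fid, process_spectrum,
                           noise_gain, peak_height_factor)
from p3nmr.nus import (make_schedule, subsample, cs_ist_reconstruct,
                       to_time_domain, zero_fill_interpolate, process_analytic_fid,
                       save_schedule, load_schedule)
from p3nmr.seeding import substream

GRID = AcqGrid((32, 128))


def one_peak(grid, snr=None, omega=(0.17, -0.23), tau=(20.0, 40.0),
             phase=(2.0, -3.0)):
    amp = 1.0
    if snr is not None:
        amp = snr * noise_gain(grid) / peak_height_factor(grid, np.array([tau]))[0]
    return SignalParams(np.array([amp]), np.array([omega]), np.array([tau]),
                        np.array([phase]))


class TestSchedules:
    def test_full_fraction_keeps_all(self):
        s = make_schedule(GRID, 1.0, "uniform_random", substream(1, "s"))
        assert s.n_kept == 32

    def test_count_rounding(self):
        g = AcqGrid((128, 16))
        s = make_schedule(g, 0.15, "uniform_random", substream(2, "s"))
        assert s.n_kept == round(0.15 * 128) == 19

    @pytest.mark.parametrize("kind", ["uniform_random", "poisson_gap"])
    def test_determinism_and_t0(self, kind):
        a = make_schedule(GRID, 0.3, kind, substream(3, "s"))
        b = make_schedule(GRID, 0.3, kind, substream(3, "s"))
        assert np.array_equal(a.indices, b.indices)
        assert [0] in a.indices.tolist()

    def test_poisson_gap_exact_count_2d(self):
        g = AcqGrid((16, 16, 64))
        s = make_schedule(g, 0.2, "poisson_gap", substream(4, "s"))
        assert s.n_kept == round(0.2 * 256)
        assert [0, 0] in s.indices.tolist()

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(GRID, 0.001, "uniform_random", substream(5, "s"))

    def test_file_round_trip(self, tmp_path):
        s = make_schedule(GRID, 0.3, "poisson_gap", substream(6, "s"))
        path = tmp_path / "nuslist"
        save_schedule(s, path)
        s2 = load_schedule(path, GRID)
        assert np.array_equal(np.sort(s.indices, axis=0), np.sort(s2.indices, axis=0))


class TestSubsample:
    def test_identity_at_full(self):
        fid = simulate_fid(one_peak(GRID), GRID)
        s = make_schedule(GRID, 1.0, "uniform_random", substream(7, "s"))
        sp = subsample(fid, s, GRID)
        assert np.array_equal(sp.fid, fid)

    def test_absent_count(self):
        fid = simulate_fid(one_peak(GRID), GRID)
        s = make_schedule(GRID, 0.25, "uniform_random", substream(8, "s"))
        sp = subsample(fid, s, GRID)
        assert (~sp.mask()).sum() == 32 - 8
        assert np.all(sp.fid[:, :, ~sp.mask(), :] == 0)


class TestCsIst:
    def test_identity_at_full_sampling(self):
        fid = simulate_fid(one_peak(GRID), GRID)
        ref = process_spectrum(fid, GRID)
        s = make_schedule(GRID, 1.0, "uniform_random", substream(9, "s"))
        rec, info = cs_ist_reconstruct(subsample(fid, s, GRID), n_iterations=30)
        assert np.abs(rec.data - ref.data).max() <= 1e-6 * np.abs(ref.data).max()

    def test_all_zero_input(self):
        s = make_schedule(GRID, 0.3, "uniform_random", substream(10, "s"))
        rec, _ = cs_ist_reconstruct(subsample(np.zeros((2, 2, 32, 128)), s, GRID),
                                    n_iterations=20)
        assert np.all(rec.data == 0)

    def test_single_peak_30pct_noisy(self):
        # SNR 50 peak, 30% NUS: position within a pixel, amplitude within 10%
        g = AcqGrid((128, 64))
        rng = substream(11, "cs")
        fid = simulate_fid(one_peak(g, snr=50), g) + rng.standard_normal((2, 2, 128, 64))
        ref = process_spectrum(fid, g)
        i_ref = np.unravel_index(np.argmax(ref.data), ref.data.shape)
        sch = make_schedule(g, 0.3, "poisson_gap", rng)
        rec, info = cs_ist_reconstruct(subsample(fid, sch, g), n_iterations=200)
        i_rec = np.unravel_index(np.argmax(rec.data), rec.data.shape)
        assert max(abs(a - b) for a, b in zip(i_rec, i_ref)) <= 1
        assert abs(rec.data[i_ref] - ref.data[i_ref]) <= 0.10 * ref.data[i_ref]

    def test_residual_monotone_and_consistent(self):
        fid = simulate_fid(one_peak(GRID), GRID)
        sch = make_schedule(GRID, 0.3, "poisson_gap", substream(12, "s"))
        sp = subsample(fid, sch, GRID)
        rec, info = cs_ist_reconstruct(sp, n_iterations=100)
        r = info["residuals"]
        assert np.all(np.diff(r) <= 1e-9 * max(r))
        # data consistency: regenerate the FID, compare on measured increments
        back = to_time_domain(rec)
        m = sp.mask()
        assert np.allclose(back[:, :, m, :], fid[:, :, m, :], atol=1e-8 * np.abs(fid).max())

    def test_error_decreases_with_fraction(self):
        g = AcqGrid((64, 32))
        rng = substream(13, "cs")
        fid = simulate_fid(one_peak(g, snr=30), g) + rng.standard_normal((2, 2, 64, 32))
        ref = process_spectrum(fid, g).data
        errs = []
        for f in (0.1, 0.3, 0.6, 1.0):
            sch = make_schedule(g, f, "poisson_gap", substream(14, f"f{f}"))
            rec, _ = cs_ist_reconstruct(subsample(fid, sch, g), n_iterations=150)
            errs.append(np.linalg.norm(rec.data - ref) / np.linalg.norm(ref))
        assert errs[-1] <= 1e-6
        assert errs[0] > errs[2]  # sparse worse than dense


class TestTimeDomain:
    def test_exact_round_trip_with_quadrature(self):
        fid = simulate_fid(one_peak(GRID), GRID)
        spec = process_spectrum(fid, GRID)
        back = to_time_domain(spec)
        assert np.allclose(back, fid, atol=1e-9 * np.abs(fid).max())

    def test_all_zero(self):
        spec = process_spectrum(np.zeros((2, 2, 32, 128)), GRID)
        assert np.all(to_time_domain(spec) == 0)

    def test_hilbert_regeneration(self):
        # regeneration from the real (absorption) data alone rebuilds the
        # full hypercomplex FID — the causality (Hilbert) relation
        # recovers each dimension's sine (dispersion) component — and the
        # round trip through processing reproduces the spectrum
        p = one_peak(GRID, omega=(0.11, -0.07), phase=(0.0, 0.0))
        fid = simulate_fid(p, GRID)
        spec = process_spectrum(fid, GRID)
        spec.quad = None
        back = to_time_domain(spec)
        assert back.shape == fid.shape
        assert np.sqrt(np.mean((back - fid) ** 2)) <= 0.01 * np.abs(fid).max()
        redo = process_spectrum(back, GRID)
        full = process_spectrum(fid, GRID)
        assert np.sqrt(np.mean((redo.data - full.data) ** 2)) \
            <= 0.01 * np.abs(full.data).max()

    def test_zero_fill_interpolation_preserves_values(self):
        fid = simulate_fid(one_peak(GRID), GRID)
        spec = process_spectrum(fid, GRID)
        fine = zero_fill_interpolate(spec, 2)
        assert fine.data.shape == (128, 512)
        # every original pixel appears at the doubled index
        assert np.allclose(fine.data[::2, ::2], spec.data, atol=1e-9 * np.abs(spec.data).max())
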