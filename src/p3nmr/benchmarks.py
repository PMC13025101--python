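"""The synthetic benchmark world: corpora and studies used for validation.

All quantitative validation runs on synthetic spectra whose stated
conditions follow the source experiments: 256 peaks per spectrum with
amplitudes log-uniform over a 1:200 dynamic range in units of the
frequency-domain noise SD (weakest peaks at one sigma), frequencies
uniform within +-0.45 cycles/dwell, relaxation times log-uniform in
[8, 128] dwell units, phases within +-5 degrees, Gaussian time-domain
noise normalized analytically so the frequency-domain SD is exactly one
sigma-unit.

The benchmark acquisition grid is 32 x 128 complex points (indirect x
direct) — a deliberate reduction of the full-size simulator default that
keeps single-CPU runtimes practical while reproducing the ~1:100
peak-to-background class ratio of 2D correlation maps (576 labeled pixels
on the 512 x 128 inference grid).  Single-peak and two-peak localization
studies use the same grid.

Training corpora keep every labeled (positive) point — the scarce
resource — and fill the remaining budget with uniformly drawn background
points; the enriched class mix is corrected back to the ~1:100 deployment
base rate by a constant logit offset at prediction time (exact for a
uniformly undersampled majority class), so the pixel probabilities stay
calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seeding import substream
from .spectra import (AcqGrid, SignalParams, Spectrum, ParamRanges, simulate_fid,
                      process_spectrum, make_label_mask, sample_spectrum_params,
                      noise_gain, peak_height_factor, peak_positions, LabelMask)
from .network import (ModelSpec, TrainConfig, MRAiModel, build_model, train,
                      extract_crosses, resample_training_points)
from .noise import NoiseSpec, make_noise

__all__ = [
    "bench_grid_2d",
    "bench_grid_3d",
    "default_ranges",
    "SpectrumBundle",
    "make_spectrum_2d",
    "make_spectrum_3d",
    "single_peak_bundle",
    "two_peak_bundle",
    "build_training_set_2d",
    "build_training_set_projection",
    "build_training_set_3d",
    "train_2d_model",
    "train_projection_model",
    "train_3d_model",
    "generate_benchmark_suite",
]

#: extra zero fill applied before probability generation (see engine)
PREPARED_ZF = 4   # standard factor 2 times the extra factor 2


def bench_grid_2d(prepared: bool = True) -> AcqGrid:
    """32 x 128 complex points (indirect, direct); zero fill 4 when prepared."""
    return AcqGrid((32, 128), zero_fill=PREPARED_ZF if prepared else 2)


def bench_grid_3d(prepared: bool = True) -> AcqGrid:
    """16 x 16 x 64 complex points; zero fill 4 when prepared."""
    return AcqGrid((16, 16, 64), zero_fill=PREPARED_ZF if prepared else 2)


def default_ranges() -> ParamRanges:
    return ParamRanges()


@dataclass
class SpectrumBundle:
    """A synthetic spectrum with its ground truth."""

    spectrum: Spectrum
    params: SignalParams
    mask: LabelMask
    fid: np.ndarray          # noisy hypercomplex FID (time-domain sigma = 1)
    sigma_time: float = 1.0

    @property
    def positions(self) -> np.ndarray:
        """Fractional peak positions on the spectrum grid."""
        return peak_positions(self.params, self.spectrum.data.shape)


def _assemble(params: SignalParams, grid: AcqGrid, rng,
              noise: NoiseSpec | None, add_time_noise: bool) -> SpectrumBundle:
    fid = simulate_fid(params, grid)
    if add_time_noise:
        fid = fid + rng.standard_normal(fid.shape)
    spectrum = process_spectrum(fid, grid)
    spectrum.sigma_noise = noise_gain(grid)
    if noise is not None:
        extra = make_noise(noise, grid, rng) * noise_gain(grid)
        spectrum = Spectrum(data=spectrum.data + extra, grid=grid,
                            quad=spectrum.quad, sigma_noise=spectrum.sigma_noise)
    mask = make_label_mask(params, spectrum)
    return SpectrumBundle(spectrum=spectrum, params=params, mask=mask, fid=fid)


def make_spectrum_2d(rng: np.random.Generator, n_peaks: int = 256,
                     grid: AcqGrid | None = None,
                     ranges: ParamRanges | None = None,
                     noise: NoiseSpec | None = None) -> SpectrumBundle:
    """2D benchmark spectrum: Gaussian time-domain noise at one sigma-unit.

    When ``noise`` is given (e.g. the bimodal projection emulation), it is
    added in the frequency domain *instead of* the time-domain noise.
    """
    grid = grid or bench_grid_2d()
    ranges = ranges or default_ranges()
    params = sample_spectrum_params(ranges, n_peaks, rng, grid=grid)
    return _assemble(params, grid, rng, noise, add_time_noise=noise is None)


def make_spectrum_3d(rng: np.random.Generator, n_peaks: int = 256,
                     grid: AcqGrid | None = None,
                     ranges: ParamRanges | None = None,
                     sign_groups: bool = True,
                     noise: NoiseSpec | None = None) -> SpectrumBundle:
    """3D benchmark spectrum.

    With ``sign_groups`` the peak set is assembled from four independently
    sampled groups with signs (+, +, -, -), emulating the sign-mixed
    training construction; ``n_peaks`` is the total across groups.
    """
    grid = grid or bench_grid_3d()
    ranges = ranges or default_ranges()
    if sign_groups:
        per = n_peaks // 4
        counts = [per, per, per, n_peaks - 3 * per]
        parts = []
        for g, (cnt, sign) in enumerate(zip(counts, (1, 1, -1, -1))):
            p = sample_spectrum_params(ranges, cnt, rng, grid=grid)
            p.sign = np.full(cnt, float(sign))
            parts.append(p)
        params = SignalParams(
            amplitude=np.concatenate([p.amplitude for p in parts]),
            omega=np.concatenate([p.omega for p in parts]),
            tau=np.concatenate([p.tau for p in parts]),
            phase_deg=np.concatenate([p.phase_deg for p in parts]),
            sign=np.concatenate([p.sign for p in parts]),
            amp_sigma=np.concatenate([p.amp_sigma for p in parts]),
        )
    else:
        params = sample_spectrum_params(ranges, n_peaks, rng, grid=grid)
    return _assemble(params, grid, rng, noise, add_time_noise=noise is None)


def single_peak_bundle(snr: float, rng: np.random.Generator,
                       grid: AcqGrid | None = None,
                       phase_deg: float = 5.0) -> SpectrumBundle:
    """One random peak at the given frequency-domain SNR (sigma-units)."""
    grid = grid or bench_grid_2d()
    ranges = ParamRanges(amp_sigma=(snr, snr), phase_deg=phase_deg)
    params = sample_spectrum_params(ranges, 1, rng, grid=grid)
    return _assemble(params, grid, rng, None, add_time_noise=True)


def two_peak_bundle(snr: float, separation_px, rng: np.random.Generator,
                    grid: AcqGrid | None = None, second_snr_factor: float = 2.0,
                    phase_deg: float = 5.0) -> SpectrumBundle:
    """Reference peak at ``snr`` plus a neighbour of twice the intensity.

    ``separation_px``: per-dimension offset of the second peak, in pixels
    of the post-zero-fill grid of the given ``grid``.
    """
    grid = grid or bench_grid_2d()
    N = np.asarray(grid.n_points, dtype=float)
    ranges = ParamRanges(amp_sigma=(snr, snr), phase_deg=phase_deg,
                         omega_margin=0.35)
    ref = sample_spectrum_params(ranges, 1, rng, grid=grid)
    ranges2 = ParamRanges(amp_sigma=(snr * second_snr_factor,) * 2,
                          phase_deg=phase_deg)
    second = sample_spectrum_params(ranges2, 1, rng, grid=grid)
    second.omega = ref.omega + np.asarray(separation_px, dtype=float) / N
    # re-calibrate the second amplitude for its own relaxation times
    second.amplitude = (second.amp_sigma * noise_gain(grid)
                        / peak_height_factor(grid, second.tau))
    params = SignalParams(
        amplitude=np.concatenate([ref.amplitude, second.amplitude]),
        omega=np.concatenate([ref.omega, second.omega]),
        tau=np.concatenate([ref.tau, second.tau]),
        phase_deg=np.concatenate([ref.phase_deg, second.phase_deg]),
        amp_sigma=np.concatenate([ref.amp_sigma, second.amp_sigma]),
    )
    params.validate()
    return _assemble(params, grid, rng, None, add_time_noise=True)


# ---------------------------------------------------------------------------
# training corpora


def _corpus(bundles, n_total: int, ratio: float, rng,
            cross_length: int = 64):
    """Training crosses: every labeled (positive) point of every bundle,
    plus uniformly drawn background points filling the corpus budget.

    Positives are the scarce resource, so all of them are kept; the
    resulting enriched class mix is corrected back to the deployment
    ratio (``ratio``) by the constant-logit-offset recalibration in the
    trainer."""
    per = int(np.ceil(n_total / len(bundles)))
    Xs, ys = [], []
    for b in bundles:
        pos = np.argwhere(b.mask.data == 1)
        neg = np.argwhere(b.mask.data == 0)
        n_neg = max(0, min(len(neg), per - len(pos)))
        keep = rng.choice(len(neg), size=n_neg, replace=False)
        idx = np.concatenate([pos, neg[keep]], axis=0)
        rng.shuffle(idx, axis=0)
        Xs.append(extract_crosses(b.spectrum, idx, cross_length))
        ys.append(b.mask.data[tuple(idx.T)].astype(np.float32))
    X = np.concatenate(Xs, axis=0)[:n_total]
    y = np.concatenate(ys, axis=0)[:n_total]
    return X, y


def build_training_set_2d(seed: int, n_spectra: int = 64, n_peaks: int = 256,
                          n_total: int = 200_000, ratio: float = 0.01,
                          grid: AcqGrid | None = None):
    rng = substream(seed, "train2d")
    bundles = [make_spectrum_2d(rng, n_peaks, grid) for _ in range(n_spectra)]
    X, y = _corpus(bundles, n_total, ratio, rng)
    return X, y


def build_training_set_projection(seed: int, n_spectra: int = 64,
                                  n_peaks: int = 256, n_total: int = 200_000,
                                  ratio: float = 0.01,
                                  grid: AcqGrid | None = None,
                                  separations=(0, 1, 2, 3, 4, 5)):
    """2D corpus with bimodal (double-Gaussian) noise emulating skylines."""
    rng = substream(seed, "trainproj")
    bundles = []
    for i in range(n_spectra):
        sep = separations[i % len(separations)]
        noise = NoiseSpec(kind="bimodal", bimodal_separation=sep)
        bundles.append(make_spectrum_2d(rng, n_peaks, grid, noise=noise))
    return _corpus(bundles, n_total, ratio, rng)


def build_training_set_3d(seed: int, n_spectra: int = 16, n_peaks: int = 256,
                          n_total: int = 200_000, ratio: float = 0.01,
                          grid: AcqGrid | None = None,
                          nus_fractions=(1.0, 0.5, 0.3, 0.15)):
    """3D corpus with the NUS-dependent Cauchy-Gaussian mixture noise."""
    rng = substream(seed, "train3d")
    grid = grid or bench_grid_3d()
    bundles = []
    for i in range(n_spectra):
        frac = nus_fractions[i % len(nus_fractions)]
        noise = NoiseSpec(kind="cauchy_gauss_mix", nus_fraction=frac)
        bundles.append(make_spectrum_3d(rng, n_peaks, grid, noise=noise))
    return _corpus(bundles, n_total, ratio, rng)


# ---------------------------------------------------------------------------
# model training at benchmark scale


def train_2d_model(seed: int, n_spectra: int = 64, n_peaks: int = 256,
                   n_total: int = 200_000, config: TrainConfig | None = None,
                   grid: AcqGrid | None = None):
    """Train the 2D model on the benchmark corpus; returns (model, history)."""
    X, y = build_training_set_2d(seed, n_spectra, n_peaks, n_total, grid=grid)
    config = config or TrainConfig(learning_rate=3e-3, lr_schedule="cosine",
                                   batch_size=4096, max_epochs=75, patience=75,
                                   recalibrate_to_ratio=0.01, seed=seed)
    model = build_model(ModelSpec(n_dims=2), seed=seed)
    return train(model, X, y, config)


def train_projection_model(seed: int, n_spectra: int = 64, n_peaks: int = 256,
                           n_total: int = 200_000,
                           config: TrainConfig | None = None,
                           grid: AcqGrid | None = None):
    X, y = build_training_set_projection(seed, n_spectra, n_peaks, n_total, grid=grid)
    config = config or TrainConfig(learning_rate=3e-3, lr_schedule="cosine",
                                   batch_size=4096, max_epochs=75, patience=75,
                                   recalibrate_to_ratio=0.01, seed=seed)
    model = build_model(ModelSpec(n_dims=2), seed=seed)
    return train(model, X, y, config)


def train_3d_model(seed: int, n_spectra: int = 16, n_peaks: int = 256,
                   n_total: int = 200_000, config: TrainConfig | None = None,
                   grid: AcqGrid | None = None):
    X, y = build_training_set_3d(seed, n_spectra, n_peaks, n_total, grid=grid)
    config = config or TrainConfig(learning_rate=3e-3, lr_schedule="cosine",
                                   batch_size=4096, max_epochs=75, patience=75,
                                   recalibrate_to_ratio=0.01, seed=seed)
    model = build_model(ModelSpec(n_dims=3), seed=seed)
    return train(model, X, y, config)


# ---------------------------------------------------------------------------
# on-disk benchmark suites


def generate_benchmark_suite(kind: str, scale: float, seed: int, out_dir):
    """Write a reproducible benchmark dataset to ``out_dir``.

    kinds: ``fig4`` (multi-peak detection suites), ``fig7_single``
    (single-peak localization at SNR 5/10/15/20), ``fig8_pair`` (two-peak
    resolution), ``fig9_ta`` (targeted-acquisition FIDs).  ``scale``
    multiplies the per-condition repetition counts (1.0 = the full stated
    counts).
    """
    import pathlib
    from .io import save_spectrum

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = substream(seed, "benchmark", kind)
    manifest = {"kind": kind, "scale": scale, "seed": seed, "items": []}
    if kind == "fig4":
        n = max(1, int(round(20 * scale)))
        for i in range(n):
            b = make_spectrum_2d(rng)
            stem = out / f"spectrum_{i:03d}"
            save_spectrum(b.spectrum, stem)
            np.savetxt(out / f"truth_{i:03d}.tsv", np.column_stack(
                [b.positions, b.params.amp_sigma]), fmt="%.6f",
                header="positions per dim..., amp_sigma")
            manifest["items"].append(stem.name)
    elif kind == "fig7_single":
        for snr in (5, 10, 15, 20):
            n = max(1, int(round(1000 * scale)))
            for i in range(n):
                b = single_peak_bundle(snr, rng)
                stem = out / f"snr{snr}_{i:04d}"
                save_spectrum(b.spectrum, stem)
                manifest["items"].append(stem.name)
    elif kind == "fig8_pair":
        n = max(1, int(round(1000 * scale)))
        for i in range(n):
            sep = rng.uniform(0, 12, size=2)
            b = two_peak_bundle(10.0, sep, rng)
            stem = out / f"pair_{i:04d}"
            save_spectrum(b.spectrum, stem)
            manifest["items"].append(stem.name)
    elif kind == "fig9_ta":
        for n_peaks in (128, 256, 512):
            b = make_spectrum_3d(rng, n_peaks=n_peaks)
            np.save(out / f"ta_fid_{n_peaks}.npy", b.fid)
            manifest["items"].append(f"ta_fid_{n_peaks}.npy")
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    import json
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
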