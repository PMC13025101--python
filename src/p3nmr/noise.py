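"""Noise families for training and testing.

Three frequency-domain noise families are used:

* ``gaussian`` — white Gaussian noise generated in the time domain and put
  through the same processing pipeline as the signal (the noise of a
  conventionally sampled spectrum);
* ``cauchy_gauss_mix`` — a weighted combination of that Gaussian noise with
  heavy-tailed Cauchy noise drawn directly in the frequency domain,
  emulating the outlier-rich baseline of CS-IST reconstructions; the
  Cauchy weight grows as the sampling fraction drops, reaching pure Cauchy
  at or below 5% NUS;
* ``bimodal`` — a symmetric double Gaussian emulating the baseline of 2D
  skyline projections of 3D spectra, with the separation between the two
  means ranging from 0 (conventional 2D) to 5 component SDs.

Because Cauchy components make the sample SD unusable, the robust scale
1.4826 * MAD is used for all normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import AcqGrid, process_spectrum, noise_gain

__all__ = [
    "NoiseSpec",
    "robust_sigma",
    "normalize_noise",
    "mixture_weights",
    "bimodal_noise",
    "make_noise",
]

#: NUS fraction at and below which the mixture is purely Cauchy.
CAUCHY_FRACTION = 0.05


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = "gaussian"  # gaussian | cauchy_gauss_mix | bimodal
    nus_fraction: float = 1.0
    bimodal_separation: float = 0.0
    target_sigma: float = 1.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "cauchy_gauss_mix", "bimodal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.target_sigma <= 0:
            raise ValueError("target_sigma must be positive")
        if self.kind == "cauchy_gauss_mix" and not (0 < self.nus_fraction <= 1):
            raise ValueError("nus_fraction must lie in (0, 1]")
        if self.kind == "bimodal" and not (0 <= self.bimodal_separation <= 5):
            raise ValueError("bimodal separation must lie in [0, 5] sigma")


def robust_sigma(x: np.ndarray) -> float:
    """1.4826 * median absolute deviation: Gaussian-consistent robust SD."""
    x = np.asarray(x, dtype=float).ravel()
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def normalize_noise(x: np.ndarray, target_sigma: float) -> np.ndarray:
    """Scale ``x`` so its robust SD equals ``target_sigma`` (idempotent)."""
    s = robust_sigma(x)
    if s == 0:
        raise ValueError("cannot normalize all-constant noise")
    return x * (target_sigma / s)


def mixture_weights(nus_fraction: float) -> tuple[float, float]:
    """(cauchy, gaussian) weights; linear schedule between 5% and 100% NUS.

    Exactly (0, 1) for fully sampled data, exactly (1, 0) for fractions
    at or below 5%, linear in between.
    """
    if not (0 < nus_fraction <= 1):
        raise ValueError("nus_fraction must lie in (0, 1]")
    cw = (1.0 - nus_fraction) / (1.0 - CAUCHY_FRACTION)
    cw = float(min(1.0, max(0.0, cw)))
    return cw, 1.0 - cw


def bimodal_noise(separation: float, sigma: float, n, rng: np.random.Generator) -> np.ndarray:
    """Equal-weight mixture of N(-separation*sigma/2, sigma) and N(+..., sigma)."""
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    shape = (n,) if np.isscalar(n) else tuple(n)
    signs = rng.choice((-1.0, 1.0), size=shape)
    return rng.normal(signs * separation * sigma / 2.0, sigma)


def _processed_gaussian(grid: AcqGrid, rng: np.random.Generator) -> np.ndarray:
    """Absorption-channel noise of a processed unit-SD time-domain FID.

    The output has SD exactly 1 by the analytic gain of the linear
    processing chain (no Monte-Carlo normalization needed).
    """
    fid = rng.standard_normal((2,) * grid.n_dims + grid.t_points)
    spec = process_spectrum(fid, grid)
    return spec.data / noise_gain(grid)


def make_noise(spec: NoiseSpec, grid: AcqGrid, rng: np.random.Generator) -> np.ndarray:
    """Frequency-domain noise on the post-zero-fill grid of ``grid``.

    The result is normalized so its robust SD equals ``spec.target_sigma``
    ("so that its SD matches the smallest possible peak amplitude" when the
    target is one sigma-unit).
    """
    shape = grid.n_points
    if spec.kind == "gaussian":
        x = _processed_gaussian(grid, rng)
    elif spec.kind == "cauchy_gauss_mix":
        cw, gw = mixture_weights(spec.nus_fraction)
        g = _processed_gaussian(grid, rng) if gw > 0 else 0.0
        # Cauchy scale chosen so its IQR matches the unit-SD Gaussian IQR
        # (quartiles +-0.6745), keeping the robust sigma stable across the
        # schedule.
        c = 0.6745 * rng.standard_cauchy(shape) if cw > 0 else 0.0
        x = cw * c + gw * g
    else:  # bimodal
        x = bimodal_noise(spec.bimodal_separation, 1.0, shape, rng)
    return normalize_noise(x, spec.target_sigma)
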