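"""Hypercomplex FID simulation and frequency-domain processing.

The time-domain model is a superposition of damped complex exponentials

    x(t_1, ..., t_n) = sum_j A_j prod_n exp(-t_n / tau_nj)
                                    exp(+-i (2 pi w_nj t_n + phi_nj))

sampled on the integer evolution-time grid t_n = 0, 1, ..., T_n - 1 (dwell
time = 1).  Frequencies are expressed in cycles per dwell, so the Nyquist
band is |w| < 0.5.  Quadrature detection in every dimension yields 2**n
real components (States convention): component (q_1, ..., q_n) carries the
product of cos (q=0) or sin (q=1) factors.

Processing follows the standard recipe: apodization, zero filling (factor
>= 2), complex FT dimension-at-a-time, with the first time-domain point
halved to suppress the DC baseline offset.  The frequency axis convention,
used everywhere in the package, is: index 0 = -Nyquist, half-open band,
w = 0 maps to index N/2.  A peak at frequency w therefore sits at
fractional grid index N * (w + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AcqGrid",
    "SignalParams",
    "Spectrum",
    "LabelMask",
    "ParamRanges",
    "apodization_window",
    "simulate_fid",
    "process_spectrum",
    "make_label_mask",
    "skyline_project",
    "sample_spectrum_params",
    "peak_height_factor",
    "noise_gain",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AcqGrid:
    """Acquisition grid: complex points per dimension, zero fill, window.

    Axes are ordered with the directly detected dimension last.
    """

    t_points: tuple[int, ...]
    zero_fill: tuple[int, ...] | int = 2
    apodization: str = "cos2"
    apod_params: dict = field(default_factory=dict)

    def __post_init__(self):
        t = tuple(int(x) for x in self.t_points)
        object.__setattr__(self, "t_points", t)
        zf = self.zero_fill
        if isinstance(zf, int):
            zf = (zf,) * len(t)
        zf = tuple(int(x) for x in zf)
        if len(zf) != len(t):
            raise ValueError("zero_fill must match number of dimensions")
        if any(z < 2 for z in zf):
            raise ValueError("zero-fill factor must be >= 2 in every dimension")
        if any(T < 2 for T in t):
            raise ValueError("need at least 2 complex points per dimension")
        object.__setattr__(self, "zero_fill", zf)

    @property
    def n_dims(self) -> int:
        return len(self.t_points)

    @property
    def n_points(self) -> tuple[int, ...]:
        """Spectrum size per dimension after zero filling."""
        return tuple(z * T for z, T in zip(self.zero_fill, self.t_points))

    def window(self, dim: int) -> np.ndarray:
        """Effective time-domain weights for ``dim`` (first point halved)."""
        w = apodization_window(self.apodization, self.t_points[dim], **self.apod_params)
        w = w.copy()
        w[0] *= 0.5
        return w

    def with_zero_fill(self, factors: tuple[int, ...] | int) -> "AcqGrid":
        return replace(self, zero_fill=factors)


def apodization_window(name: str, T: int, **params) -> np.ndarray:
    """Time-domain apodization window of length ``T``.

    ``cos2`` (default) is cos^2(pi t / 2T): unity at t=0, decaying to ~0 at
    the truncation point, which keeps the processed line of a non-decaying
    signal within ~2 grid points FWHM at zero-fill 2.
    """
    t = np.arange(T)
    if name == "cos2":
        return np.cos(np.pi * t / (2 * T)) ** 2
    if name == "cos":
        return np.cos(np.pi * t / (2 * T))
    if name == "none":
        return np.ones(T)
    raise ValueError(f"unknown apodization window {name!r}")


@dataclass
class SignalParams:
    """Per-peak parameters of the exponential model.

    amplitude : (J,) positive time-domain amplitudes A_j
    omega     : (J, n) frequencies in cycles per dwell, |w| < 0.5
    tau       : (J, n) relaxation times in dwell units, > 0
    phase_deg : (J, n) phases in degrees
    sign      : (J,) +1 or -1, the overall sign of each peak
    amp_sigma : optional (J,) ground-truth peak heights in noise-sigma
                units (bookkeeping written by the samplers; not used by
                the simulator itself)
    """

    amplitude: np.ndarray
    omega: np.ndarray
    tau: np.ndarray
    phase_deg: np.ndarray
    sign: np.ndarray | None = None
    amp_sigma: np.ndarray | None = None

    def __post_init__(self):
        self.amplitude = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))
        self.phase_deg = np.atleast_2d(np.asarray(self.phase_deg, dtype=float))
        if self.sign is None:
            self.sign = np.ones_like(self.amplitude)
        else:
            self.sign = np.atleast_1d(np.asarray(self.sign, dtype=float))

    @property
    def n_peaks(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_dims(self) -> int:
        return self.omega.shape[1]

    def validate(self) -> None:
        if self.n_peaks == 0:
            return
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitudes must be positive")
        if np.any(self.tau <= 0):
            raise ValueError("relaxation times must be positive")
        if np.any(np.abs(self.omega) >= 0.5):
            raise ValueError("frequencies must lie inside the Nyquist band |w| < 0.5")
        if not np.all(np.isin(self.sign, (-1.0, 1.0))):
            raise ValueError("sign must be +1 or -1")

    @staticmethod
    def empty(n_dims: int) -> "SignalParams":
        z = np.zeros((0,))
        return SignalParams(z, np.zeros((0, n_dims)), np.ones((0, n_dims)),
                            np.zeros((0, n_dims)), np.ones((0,)))


@dataclass
class Spectrum:
    """Processed real (absorption) spectrum with retained quadrature data.

    data  : real nD array on the post-zero-fill grid
    quad  : optional (2,)*n + data.shape array holding all 2**n quadrature
            components; component (0,...,0) equals ``data``
    grid  : the acquisition grid the spectrum was processed from
    sigma_noise : frequency-domain noise SD, when known
    """

    data: np.ndarray
    grid: AcqGrid
    quad: np.ndarray | None = None
    sigma_noise: float | None = None

    def __post_init__(self):
        expect = self.grid.n_points
        if tuple(self.data.shape) != expect:
            raise ValueError(f"data shape {self.data.shape} != post-zero-fill {expect}")
        if self.quad is not None:
            qshape = (2,) * self.grid.n_dims + expect
            if tuple(self.quad.shape) != qshape:
                raise ValueError("quadrature array shape mismatch")

    @property
    def n_dims(self) -> int:
        return self.data.ndim

    def robust_sigma(self) -> float:
        from .noise import robust_sigma
        if self.sigma_noise is not None:
            return float(self.sigma_noise)
        return robust_sigma(self.data)


@dataclass
class LabelMask:
    """Binary array marking peak-maximum grid points."""

    data: np.ndarray

    def __post_init__(self):
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("label mask must be binary")
        self.data = self.data.astype(np.uint8)

    @property
    def n_positive(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# simulation


def _dim_trig(params: SignalParams, dim: int, T: int) -> np.ndarray:
    """(J, 2, T) array of decayed cos/sin factors for one dimension."""
    t = np.arange(T)
    arg = 2 * np.pi * params.omega[:, dim, None] * t + np.deg2rad(params.phase_deg)[:, dim, None]
    decay = np.exp(-t / params.tau[:, dim, None])
    return np.stack([np.cos(arg) * decay, np.sin(arg) * decay], axis=1)


def simulate_fid(params: SignalParams, grid: AcqGrid) -> np.ndarray:
    """Hypercomplex FID of shape (2,)*n + t_points.

    Component (q_1,...,q_n) = sum_j sign_j A_j prod_n [cos,sin][q_n] with
    the decayed arguments 2 pi w t + phi.
    """
    params.validate()
    n = grid.n_dims
    if params.n_peaks and params.n_dims != n:
        raise ValueError("parameter dimensionality does not match grid")
    out = np.zeros((2,) * n + grid.t_points)
    if params.n_peaks == 0:
        return out
    factors = [_dim_trig(params, d, grid.t_points[d]) for d in range(n)]
    amp = params.sign * params.amplitude
    if n == 2:
        out += np.einsum("j,jau,jbv->abuv", amp, factors[0], factors[1], optimize=True)
    elif n == 3:
        out += np.einsum("j,jau,jbv,jcw->abcuvw", amp, factors[0], factors[1],
                         factors[2], optimize=True)
    else:
        raise ValueError("only 2D and 3D grids are supported")
    return out


def process_spectrum(fid: np.ndarray, grid: AcqGrid) -> Spectrum:
    """Apodize, zero fill, FT and quadrature-split the hypercomplex FID."""
    n = grid.n_dims
    if tuple(fid.shape) != (2,) * n + grid.t_points:
        raise ValueError("FID shape does not match grid")
    X = np.asarray(fid, dtype=float)
    for d in range(n):
        z = np.take(X, 0, axis=d) + 1j * np.take(X, 1, axis=d)
        axis = (n - 1) + d
        w = grid.window(d)
        shape = [1] * z.ndim
        shape[axis] = len(w)
        z = z * w.reshape(shape)
        z = np.fft.fft(z, n=grid.n_points[d], axis=axis)
        z = np.fft.fftshift(z, axes=axis)
        X = np.stack([z.real, z.imag], axis=d)
    absorption = X[(0,) * n]
    return Spectrum(data=absorption, grid=grid, quad=X)


def peak_height_factor(grid: AcqGrid, tau: np.ndarray) -> np.ndarray:
    """On-resonance processed peak height per unit time-domain amplitude.

    For a zero-phase peak the spectrum maximum is (up to a small off-grid
    scalloping loss) the product over dimensions of sum_t w_eff(t) e^{-t/tau}.
    ``tau`` has shape (..., n).
    """
    tau = np.asarray(tau, dtype=float)
    h = np.ones(tau.shape[:-1])
    for d in range(grid.n_dims):
        t = np.arange(grid.t_points[d])
        w = grid.window(d)
        h = h * np.sum(w * np.exp(-t / tau[..., d, None]), axis=-1)
    return h


def noise_gain(grid: AcqGrid) -> float:
    """Frequency-domain noise SD produced by unit-SD time-domain noise.

    Processing is linear and every output pixel is the same weighted sum of
    iid time-domain samples, so the gain is sqrt(prod_n sum_t w_eff(t)^2).
    """
    g = 1.0
    for d in range(grid.n_dims):
        g *= float(np.sum(grid.window(d) ** 2))
    return float(np.sqrt(g))


# ---------------------------------------------------------------------------
# labels and projections


def peak_positions(params: SignalParams, shape: Sequence[int]) -> np.ndarray:
    """Fractional grid positions (J, n) of the peak maxima: N (w + 0.5)."""
    N = np.asarray(shape, dtype=float)
    return N * (params.omega + 0.5)


def _label_indices_1d(f: float, N: int) -> list[int]:
    i0 = int(np.floor(f))
    r = f - i0
    if 0.25 <= r <= 0.75:
        idx = [i0, i0 + 1]
    else:
        idx = [i0 if r < 0.25 else i0 + 1]
    idx = [i for i in idx if 0 <= i < N]
    if not idx:  # edge case: keep the nearest in-grid index
        idx = [min(max(int(round(f)), 0), N - 1)]
    return idx


def make_label_mask(params: SignalParams, spectrum: Spectrum) -> LabelMask:
    """Ones at the grid indices nearest each peak maximum.

    When the fractional position lies 0.25-0.75 between two indices in a
    dimension, both adjacent indices are labeled; a dual-label partner that
    falls off the grid is dropped.
    """
    shape = spectrum.data.shape
    mask = np.zeros(shape, dtype=np.uint8)
    pos = peak_positions(params, shape)
    for j in range(params.n_peaks):
        sets = [_label_indices_1d(pos[j, d], shape[d]) for d in range(len(shape))]
        mesh = np.meshgrid(*sets, indexing="ij")
        mask[tuple(m.ravel() for m in mesh)] = 1
    return LabelMask(mask)


def skyline_project(spectrum: Spectrum, dropped_axis: int) -> Spectrum:
    """Element-wise maximum over ``dropped_axis`` (skyline convention)."""
    n = spectrum.n_dims
    if n < 2:
        raise ValueError("skyline projection needs at least 2 dimensions")
    if not (0 <= dropped_axis < n):
        raise ValueError(f"invalid axis {dropped_axis} for a {n}D spectrum")
    data = spectrum.data.max(axis=dropped_axis)
    keep = [d for d in range(n) if d != dropped_axis]
    grid = AcqGrid(
        t_points=tuple(spectrum.grid.t_points[d] for d in keep),
        zero_fill=tuple(spectrum.grid.zero_fill[d] for d in keep),
        apodization=spectrum.grid.apodization,
        apod_params=spectrum.grid.apod_params,
    )
    return Spectrum(data=data, grid=grid, quad=None, sigma_noise=None)


# ---------------------------------------------------------------------------
# random parameter sampling


@dataclass(frozen=True)
class ParamRanges:
    """Sampling ranges emulating 2D 1H-15N / 3D 1H-15N-13C correlation maps.

    Amplitudes are log-uniform over a 1:200 dynamic range in units of the
    frequency-domain noise SD, the weakest peaks sitting at one sigma.
    Frequencies are uniform within +-omega_margin cycles/dwell; relaxation
    times log-uniform in dwell units; phases uniform in +-phase_deg.
    """

    amp_sigma: tuple[float, float] = (1.0, 200.0)
    tau: tuple[float, float] = (8.0, 128.0)
    omega_margin: float = 0.45
    phase_deg: float = 5.0

    def validate(self) -> None:
        for lo, hi in (self.amp_sigma, self.tau):
            if not (0 < lo <= hi):
                raise ValueError("ranges must satisfy 0 < min <= max")
        if not (0 < self.omega_margin < 0.5):
            raise ValueError("omega_margin must lie in (0, 0.5)")
        if self.phase_deg < 0:
            raise ValueError("phase range must be nonnegative")


def sample_spectrum_params(
    ranges: ParamRanges,
    n_peaks: int,
    rng: np.random.Generator,
    grid: AcqGrid | None = None,
    n_dims: int | None = None,
) -> SignalParams:
    """Draw ``n_peaks`` random peaks.

    When ``grid`` is given, the sampled sigma-unit amplitudes are converted
    to time-domain amplitudes such that each processed peak height equals
    its amplitude times the frequency-domain noise SD; the sigma-unit draw
    is kept in ``amp_sigma`` for ground-truth SNR bookkeeping.
    """
    ranges.validate()
    if grid is not None:
        n_dims = grid.n_dims
    if n_dims is None:
        raise ValueError("provide either grid or n_dims")
    lo, hi = ranges.amp_sigma
    amp_sigma = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_peaks))
    tlo, thi = ranges.tau
    tau = np.exp(rng.uniform(np.log(tlo), np.log(thi), size=(n_peaks, n_dims)))
    omega = rng.uniform(-ranges.omega_margin, ranges.omega_margin, size=(n_peaks, n_dims))
    phase = rng.uniform(-ranges.phase_deg, ranges.phase_deg, size=(n_peaks, n_dims))
    if grid is not None:
        amplitude = amp_sigma * noise_gain(grid) / peak_height_factor(grid, tau)
    else:
        amplitude = amp_sigma.copy()
    return SignalParams(amplitude=amplitude, omega=omega, tau=tau, phase_deg=phase,
                        amp_sigma=amp_sigma)
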