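"""End-to-end peak-probability inference.

2D spectra are scored directly by the 2D model.  For 3D spectra the class
imbalance (peak maxima are ~1 : 10^4 of the grid) makes a direct run
impractical, so inference is staged: probability maps are first computed
for the three orthogonal 2D skyline projections (models trained with the
bimodal projection noise), each 3D point receives a preliminary score —
the element-wise product of its projected probabilities — and points whose
geometric mean over the used projections exceeds 2.5% become the region of
interest evaluated by the sensitive 3D model.  A high-sensitivity support
spectrum (e.g. a 2D HSQC) can replace any skyline projection in the ROI
stage ("hyperdimensional coprocessing").

All inference is preceded by an extra two-fold zero filling of the input
spectrum (Fourier interpolation), which sharpens the probability features
used for sub-pixel peak refinement; because cross-objectives are scaled by
the robust noise sigma, inference is invariant to any positive rescaling
of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import AcqGrid, Spectrum, skyline_project
from .nus import (SamplingSchedule, make_schedule, subsample, cs_ist_reconstruct,
                  zero_fill_interpolate)
from .network import MRAiModel, predict_map
from .peaks import pick

__all__ = [
    "P3Map",
    "ROIMask",
    "prepare_spectrum",
    "p3_2d",
    "roi_3d",
    "p3_3d",
    "coprocess_support",
    "ta_buildup",
]

#: extra zero-fill factor applied before probability generation
P3_ZERO_FILL = 2

#: geometric-mean probability threshold selecting the 3D region of interest
ROI_THRESHOLD = 0.025


@dataclass
class P3Map:
    """Per-point peak-maximum probabilities on the (prepared) spectrum grid."""

    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ROIMask:
    """Region-of-interest mask on the prepared 3D grid."""

    mask: np.ndarray
    threshold: float
    score: np.ndarray          # preliminary per-point probability product
    spectrum: Spectrum         # the prepared 3D spectrum the mask refers to
    n_projections: int = 3


def prepare_spectrum(spectrum: Spectrum, factor: int = P3_ZERO_FILL) -> Spectrum:
    """Extra zero filling (Fourier interpolation) before P3 generation."""
    return zero_fill_interpolate(spectrum, factor)


def p3_2d(spectrum: Spectrum, model_2d: MRAiModel, prepared: bool = False) -> P3Map:
    """Direct 2D probability map."""
    if spectrum.n_dims != 2:
        raise ValueError("p3_2d expects a 2D spectrum")
    if model_2d.spec.n_dims != 2:
        raise ValueError("p3_2d expects a 2D model")
    spec = spectrum if prepared else prepare_spectrum(spectrum)
    data = predict_map(model_2d, spec)
    return P3Map(data=data, provenance={"stage": "2d", "prepared": True})


def _projection_maps(spec3: Spectrum, projection_models, support_maps) -> dict:
    """P3 maps of the three orthogonal skyline projections (or supports)."""
    maps = {}
    for axis in range(3):
        if support_maps is not None and axis in support_maps:
            maps[axis] = np.asarray(support_maps[axis], dtype=np.float32)
            continue
        proj = skyline_project(spec3, axis)
        model = projection_models[axis] if isinstance(projection_models, (list, tuple, dict)) \
            else projection_models
        maps[axis] = predict_map(model, proj)
    shape = spec3.data.shape
    for axis, m in maps.items():
        expect = tuple(s for d, s in enumerate(shape) if d != axis)
        if m.shape != expect:
            raise ValueError(f"projection map for axis {axis} has shape {m.shape}, "
                             f"expected {expect}")
    return maps


def roi_3d(spectrum_3d: Spectrum, projection_models, support_maps: dict | None = None,
           threshold: float = ROI_THRESHOLD, prepared: bool = False) -> ROIMask:
    """Region of interest from the product of projected probabilities.

    The stored preliminary score is the product over the used projections;
    the mask keeps points whose geometric mean (k-th root of the product)
    exceeds ``threshold``.
    """
    if spectrum_3d.n_dims != 3:
        raise ValueError("roi_3d expects a 3D spectrum")
    spec3 = spectrum_3d if prepared else prepare_spectrum(spectrum_3d)
    maps = _projection_maps(spec3, projection_models, support_maps)
    k = len(maps)
    if k < 2:
        raise ValueError("at least two projections are required")
    score = np.ones(spec3.data.shape, dtype=np.float64)
    for axis, m in maps.items():
        score *= np.expand_dims(m, axis=axis)
    mask = score > threshold ** k
    return ROIMask(mask=mask, threshold=threshold, score=score,
                   spectrum=spec3, n_projections=k)


def p3_3d(roi: ROIMask, model_3d: MRAiModel) -> P3Map:
    """3D probabilities inside the ROI; exactly zero outside."""
    if model_3d.spec.n_dims != 3:
        raise ValueError("p3_3d expects a 3D model")
    prov = {"stage": "3d", "roi_threshold": roi.threshold,
            "roi_points": int(roi.mask.sum())}
    if not roi.mask.any():
        prov["warning"] = "empty ROI"
        return P3Map(np.zeros(roi.spectrum.data.shape, dtype=np.float32), prov)
    data = predict_map(model_3d, roi.spectrum, roi_mask=roi.mask)
    return P3Map(data=data, provenance=prov)


def coprocess_support(support_spectrum: Spectrum, model_2d: MRAiModel,
                      target_shape: tuple[int, ...], prepared: bool = False) -> np.ndarray:
    """P3 map of a support 2D spectrum, for use in place of a projection.

    The prepared support map must land exactly on the corresponding
    projection grid of the prepared 3D spectrum (index mapping, no
    interpolation); a size mismatch is rejected.
    """
    m = p3_2d(support_spectrum, model_2d, prepared=prepared)
    if m.data.shape != tuple(target_shape):
        raise ValueError(f"support map shape {m.data.shape} does not match the "
                         f"projection grid {tuple(target_shape)}")
    return m.data


def ta_buildup(fid: np.ndarray, grid: AcqGrid, fractions,
               projection_models, model_3d: MRAiModel,
               support_maps: dict | None = None, cutoff: float = 0.20,
               threshold: float = ROI_THRESHOLD, n_iterations: int = 100,
               schedule_kind: str = "poisson_gap",
               rng: np.random.Generator | None = None) -> list[dict]:
    """Targeted-acquisition build-up: peak counts vs sampling fraction.

    For each fraction: draw a schedule, subsample the FID, reconstruct with
    CS-IST, run the staged 3D inference (optionally with support maps) and
    count picked peaks at the conservative probability cutoff (20% by
    default).  A count is reported for every requested fraction.
    """
    fr = list(fractions)
    if any(b <= a for a, b in zip(fr, fr[1:])):
        raise ValueError("fractions must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for f in fr:
        schedule = make_schedule(grid, f, schedule_kind, rng)
        sparse = subsample(fid, schedule, grid)
        spectrum, info = cs_ist_reconstruct(sparse, n_iterations=n_iterations)
        roi = roi_3d(spectrum, projection_models, support_maps, threshold)
        p3 = p3_3d(roi, model_3d)
        peaks = pick(p3.data, cutoff)
        out.append({"fraction": f, "count": len(peaks),
                    "roi_points": int(roi.mask.sum()),
                    "converged": info["converged"]})
    return out
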