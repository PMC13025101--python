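"""Portable spectrum container: raw binary array + structured-text header.

A spectrum is stored as ``<stem>.dat`` (float32, little-endian, C order)
with a ``<stem>.json`` sidecar describing shape, byte order, the
acquisition grid and the noise sigma.  Quadrature components, when
retained, go to ``<stem>.quad.dat`` with the shape recorded in the header.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np

from .spectra import AcqGrid, Spectrum

__all__ = ["save_spectrum", "load_spectrum"]

_FORMAT = "p3nmr-spectrum-v1"


def save_spectrum(spectrum: Spectrum, stem) -> None:
    stem = pathlib.Path(stem)
    data = np.ascontiguousarray(spectrum.data, dtype="<f4")
    data.tofile(stem.with_suffix(".dat"))
    header = {
        "format": _FORMAT,
        "dtype": "float32",
        "byte_order": "little-endian",
        "order": "C",
        "shape": list(spectrum.data.shape),
        "grid": {
            "t_points": list(spectrum.grid.t_points),
            "zero_fill": list(spectrum.grid.zero_fill),
            "apodization": spectrum.grid.apodization,
            "apod_params": spectrum.grid.apod_params,
        },
        "sigma_noise": spectrum.sigma_noise,
        "has_quadrature": spectrum.quad is not None,
    }
    if spectrum.quad is not None:
        np.ascontiguousarray(spectrum.quad, dtype="<f4").tofile(
            stem.with_suffix(".quad.dat"))
        header["quad_shape"] = list(spectrum.quad.shape)
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_spectrum(stem) -> Spectrum:
    stem = pathlib.Path(stem)
    try:
        header = json.loads(stem.with_suffix(".json").read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed header {stem.with_suffix('.json')}: "
                         f"line {e.lineno}, column {e.colno}") from e
    if header.get("format") != _FORMAT:
        raise ValueError(f"not a {_FORMAT} header: {stem}")
    shape = tuple(header["shape"])
    if len(shape) not in (2, 3):
        raise ValueError(f"unsupported dimensionality {len(shape)} "
                         "(only 2D and 3D spectra are supported)")
    grid = AcqGrid(
        t_points=tuple(header["grid"]["t_points"]),
        zero_fill=tuple(header["grid"]["zero_fill"]),
        apodization=header["grid"]["apodization"],
        apod_params=header["grid"]["apod_params"],
    )
    data = np.fromfile(stem.with_suffix(".dat"), dtype="<f4").reshape(shape)
    quad = None
    if header.get("has_quadrature"):
        quad = np.fromfile(stem.with_suffix(".quad.dat"), dtype="<f4").reshape(
            tuple(header["quad_shape"])).astype(float)
    return Spectrum(data=data.astype(float), grid=grid, quad=quad,
                    sigma_noise=header.get("sigma_noise"))
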