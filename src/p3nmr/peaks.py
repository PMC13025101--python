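"""Probability-based peak picking with sub-pixel refinement.

A candidate peak is a grid point of the probability map that is strictly
greater than all of its face-and-diagonal neighbours and at least the
probability cutoff.  Its coordinates are then refined per dimension by
three-point quadratic interpolation,

    delta = (y[-1] - y[+1]) / (2 (y[-1] - 2 y[0] + y[+1])),

clipped to (-0.5, 0.5).  Exact plateaus yield no maximum (deterministic
tie policy); edge maxima are kept unrefined in the edge dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PeakList", "find_local_maxima", "refine_quadratic", "pick"]


@dataclass
class PeakList:
    """Picked peaks: integer seed index, sub-pixel position, probability."""

    seeds: np.ndarray      # (m, n) int
    positions: np.ndarray  # (m, n) float, fractional grid indices
    probabilities: np.ndarray  # (m,)

    def __len__(self) -> int:
        return len(self.probabilities)

    def to_tsv(self, path, axis_labels=None) -> None:
        n = self.seeds.shape[1] if len(self) else 0
        labels = axis_labels or [f"dim{d}" for d in range(n)]
        with open(path, "w") as fh:
            fh.write("\t".join([f"pos_{l}" for l in labels] + ["probability"]) + "\n")
            for pos, p in zip(self.positions, self.probabilities):
                fh.write("\t".join(f"{x:.4f}" for x in pos) + f"\t{p:.6f}\n")


def find_local_maxima(p3: np.ndarray, cutoff: float) -> np.ndarray:
    """Indices (m, n) of strict local maxima with value >= cutoff."""
    if not (0 <= cutoff <= 1):
        raise ValueError("cutoff must lie in [0, 1]")
    p3 = np.asarray(p3)
    footprint = np.ones((3,) * p3.ndim, dtype=bool)
    footprint[(1,) * p3.ndim] = False
    neigh = ndimage.maximum_filter(p3, footprint=footprint, mode="constant", cval=-np.inf)
    is_max = (p3 > neigh) & (p3 >= cutoff)
    return np.argwhere(is_max)


def refine_quadratic(p3: np.ndarray, index) -> np.ndarray:
    """Sub-pixel position of a local maximum (fractional grid indices)."""
    p3 = np.asarray(p3)
    idx = tuple(int(i) for i in np.atleast_1d(index))
    pos = np.array(idx, dtype=float)
    for d in range(p3.ndim):
        i = idx[d]
        if i == 0 or i == p3.shape[d] - 1:
            continue  # edge: no refinement in this dimension
        sel = list(idx)
        sel[d] = i - 1
        ym = p3[tuple(sel)]
        y0 = p3[idx]
        sel[d] = i + 1
        yp = p3[tuple(sel)]
        denom = 2.0 * (ym - 2.0 * y0 + yp)
        if denom == 0:
            continue  # zero curvature: keep the grid position
        delta = (ym - yp) / denom
        pos[d] = i + float(np.clip(delta, -0.4999, 0.4999))
    return pos


def pick(p3: np.ndarray, cutoff: float = 0.5) -> PeakList:
    """Local maxima + quadratic refinement, sorted by probability (desc)."""
    seeds = find_local_maxima(p3, cutoff)
    if len(seeds) == 0:
        n = np.asarray(p3).ndim
        return PeakList(np.zeros((0, n), dtype=int), np.zeros((0, n)), np.zeros(0))
    probs = np.asarray(p3)[tuple(seeds.T)]
    order = np.argsort(-probs, kind="stable")
    seeds = seeds[order]
    probs = probs[order]
    positions = np.array([refine_quadratic(p3, s) for s in seeds])
    return PeakList(seeds=seeds, positions=positions, probabilities=probs)
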