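"""Deterministic per-stage random substreams.

All randomness in the package flows from a single integer seed.  Each
pipeline stage derives its own independent generator by hashing the stage
name, so adding a stage never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a generator for the substream identified by ``names``.

    The stage names are hashed with CRC-32, which is stable across runs,
    platforms and Python versions (unlike the built-in ``hash``).
    """
    keys = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(n.encode("utf-8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))
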