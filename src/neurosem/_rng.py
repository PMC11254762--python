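"""Deterministic seed-splitting helpers.

All stochastic stages in the package draw from a single integer seed. Each
stage derives an independent child stream by hashing the root seed together
with a string tag, so adding a stage never perturbs the streams of existing
ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(seed: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from a root seed and a tag path."""
    key = "/".join(str(t) for t in tags)
    return (int(seed) ^ zlib.crc32(key.encode())) % (2**31 - 1)


def rng_for(seed: int, *tags: object) -> np.random.Generator:
    """A generator seeded from `seed` and a stage tag path."""
    return np.random.default_rng(np.random.SeedSequence(child_seed(seed, *tags)))
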