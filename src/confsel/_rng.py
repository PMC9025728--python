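"""Seed-substream management.

Every stochastic stage (splitting, SMOTE, random filters, synthetic data)
draws from its own named substream of a single master seed, so that
changing one stage's consumption of randomness never perturbs another's.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a CRC32 of the name, so the mapping is stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
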