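"""Seed fan-out for reproducible, stage-independent random substreams.

A single global seed is combined with stage-name keys (hashed to stable
32-bit integers) so that every pipeline stage draws from its own substream:
adding or reordering a stage never perturbs another stage's draws, and any
stage can be reproduced in isolation from (seed, stage keys).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "key_to_int"]


def key_to_int(key) -> int:
    """Stable non-negative 32-bit integer from a string or int key."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode()) & 0x7FFFFFFF


def stage_rng(seed: int, *keys) -> np.random.Generator:
    """A PCG64 generator keyed by (seed, *keys)."""
    entropy = [int(seed) & 0x7FFFFFFF] + [key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
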