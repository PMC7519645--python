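"""Seed plumbing: one global seed expands deterministically into component seeds."""

from __future__ import annotations

import zlib

import numpy as np

_SEED_MOD = 2**31 - 1


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a child seed (< 2**31) from a global seed and a label path.

    Stable across processes and platforms (CRC32 of the token string),
    so e.g. (seed, "fold", 3) always maps to the same child seed.
    """
    label = "/".join(str(t) for t in tokens)
    h = zlib.crc32(label.encode("utf-8"))
    return (int(seed) * 1_000_003 + h) % _SEED_MOD


def rng_for(seed: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *tokens))
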