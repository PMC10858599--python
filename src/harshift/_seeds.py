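"""Deterministic seed derivation for named pipeline stages."""

from __future__ import annotations

import zlib

import numpy as np

_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def derive_seed(seed: int, *names: str | int) -> int:
    """Derive a reproducible sub-seed from a master seed and stage names.

    Subject/stage streams must not collide and must not depend on cohort
    size, so each name is hashed with CRC32 and folded into the seed.
    """
    out = int(seed) & _MASK
    for name in names:
        out ^= zlib.crc32(str(name).encode("utf-8"))
    return out & _MASK


def rng_for(seed: int, *names: str | int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *names))
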