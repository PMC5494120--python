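"""Deterministic seed fan-out.

A single master seed is expanded into per-stage / per-fold / per-repeat
seeds through :class:`numpy.random.SeedSequence` spawn keys, so no two
stages ever share a stream and no hidden global RNG state is used.
String keys are hashed with CRC-32 so stage names participate in the key.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key)


def derive_seed(master: int, *keys: int | str) -> int:
    """Derive a child seed (< 2**31) from a master seed and a key path."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(_key_to_int(k) for k in keys))
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)
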