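"""Deterministic child-seed derivation.

All randomness in the package flows from explicit integer seeds through
:func:`child_rng`, so that every stage of a pipeline can be re-run in
isolation and reproduce its output bit-identically.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"seed key must be int or str, got {type(key).__name__}")


def child_seed_sequence(seed: int, *keys: object) -> np.random.SeedSequence:
    """SeedSequence for a (seed, *keys) address in the derivation tree."""
    return np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *(_key_to_int(k) for k in keys)])


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Generator seeded deterministically from a master seed and a key path.

    Keys may be integers (e.g. subject index) or strings (stage names);
    strings are hashed with CRC32 so the derivation is stable across runs
    and processes.
    """
    return np.random.default_rng(child_seed_sequence(seed, *keys))
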