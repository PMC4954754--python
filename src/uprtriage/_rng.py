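"""Seed derivation: one master seed fans out to a named stream per table type."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["named_rng"]


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Return a generator for stream ``name`` derived from ``seed``.

    The stream key is a CRC32 of the name, so two differently named streams
    under the same master seed are statistically independent and each
    (seed, name) pair is reproducible on its own.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
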