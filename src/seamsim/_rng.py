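"""Deterministic random-stream management.

A single master seed governs every stochastic stage of a run.  Named
substreams are derived with ``SeedSequence`` spawn keys, so enabling,
disabling, or reordering one stage never shifts the draws consumed by
another, and parallel execution order cannot change results.
"""

from __future__ import annotations

import zlib
from typing import Union

import numpy as np

SeedLike = Union[int, np.random.SeedSequence]


def _key(part) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("substream keys must be non-negative")
        return int(part)
    return zlib.crc32(str(part).encode("utf-8"))


def substream(seed: SeedLike, *path) -> np.random.Generator:
    """Return the generator for the named substream ``path`` under ``seed``.

    ``path`` components may be ints or strings (strings are hashed with
    CRC-32).  The same (seed, path) pair always yields the same stream.
    """
    if isinstance(seed, np.random.SeedSequence):
        base = seed
    else:
        base = np.random.SeedSequence(int(seed))
    key = tuple(_key(p) for p in path)
    ss = np.random.SeedSequence(entropy=base.entropy, spawn_key=base.spawn_key + key)
    return np.random.default_rng(ss)


def as_generator(rng: Union[SeedLike, np.random.Generator, None]) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator, or None to a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        return np.random.default_rng()
    return substream(rng)
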