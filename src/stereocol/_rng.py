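"""Seed-splitting utilities.

All randomness in the package flows from a single integer seed. Independent
streams for different stages/subjects are derived by hashing a path of string
or integer labels into a ``SeedSequence`` spawn key, so that adding or
reordering stages does not perturb the streams of unrelated stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["split_rng", "split_seed"]


def _key(path: tuple) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(p).encode()) for p in path)


def split_rng(seed: int, *path) -> np.random.Generator:
    """Return a generator for stream ``path`` under the master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=_key(path)))


def split_seed(seed: int, *path) -> int:
    """Derive a child integer seed (< 2**31) for stream ``path``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_key(path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
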