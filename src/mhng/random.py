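"""Named, reproducible random streams.

Every source of randomness in the package is a :class:`numpy.random.Generator`
derived from a single master seed and a string path naming the consumer
(e.g. ``("game", "pair3", "decisions")``).  Identical (seed, path) pairs yield
identical streams; distinct paths yield independent streams.  A module-level
registry records every stream handed out, so tests can audit that no component
draws from an unnamed (hence unseeded) source.
"""

from __future__ import annotations

import zlib
from typing import Iterable

import numpy as np

# audit trail: (master_seed, path) -> number of times the stream was created
STREAM_REGISTRY: dict[tuple[int, tuple[str, ...]], int] = {}


def _path_key(name: str) -> int:
    # stable across processes (unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def derive_rng(master_seed: int, *path: str) -> np.random.Generator:
    """Return the generator for stream ``path`` under ``master_seed``."""
    if not path:
        raise ValueError("a stream needs at least one path component")
    key = (int(master_seed), tuple(path))
    STREAM_REGISTRY[key] = STREAM_REGISTRY.get(key, 0) + 1
    entropy = [int(master_seed)] + [_path_key(p) for p in path]
    return np.random.default_rng(entropy)


def spawn_seeds(master_seed: int, n: int, *path: str) -> list[int]:
    """Derive ``n`` child seeds (each < 2**31) for sub-components."""
    rng = derive_rng(master_seed, *path, "spawn")
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def clear_registry() -> None:
    STREAM_REGISTRY.clear()


def registered_streams(master_seed: int | None = None) -> list[tuple[str, ...]]:
    keys: Iterable = STREAM_REGISTRY
    if master_seed is not None:
        keys = (k for k in STREAM_REGISTRY if k[0] == master_seed)
    return sorted(k[1] for k in keys)
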