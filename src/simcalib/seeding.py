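"""Hierarchical, counter-based seeding.

Every source of randomness in a run is derived from one root seed through a
named tree of :class:`numpy.random.SeedSequence` spawn keys, so any single
stage / practitioner / repetition can be re-created in isolation and two runs
with the same root seed are bit-identical.

Stage names are mapped to stable integers via CRC-32 so the scheme does not
depend on Python's per-process hash randomisation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_sequence", "child_rng", "child_int_seed"]


def _key(part: int | str) -> int:
    if isinstance(part, int):
        if part < 0:
            raise ValueError("seed-tree keys must be non-negative")
        return part
    return zlib.crc32(part.encode("utf-8"))


def child_sequence(root_seed: int, *path: int | str) -> np.random.SeedSequence:
    """SeedSequence for the node at ``path`` under ``root_seed``.

    ``path`` mixes stage names (strings) and counters (ints), e.g.
    ``child_sequence(42, "truth", 17)`` is the stream for ground-truth
    repetition 17.
    """
    return np.random.SeedSequence(root_seed, spawn_key=tuple(_key(p) for p in path))


def child_rng(root_seed: int, *path: int | str) -> np.random.Generator:
    """A fresh ``numpy`` Generator for the node at ``path``."""
    return np.random.default_rng(child_sequence(root_seed, *path))


def child_int_seed(root_seed: int, *path: int | str) -> int:
    """A plain integer seed (< 2**31) for libraries that take one."""
    return int(child_sequence(root_seed, *path).generate_state(1)[0] % (2**31))
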