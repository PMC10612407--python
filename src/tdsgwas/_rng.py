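"""Named random substreams.

Every source of randomness in the package is derived from one master seed via
``SeedSequence`` spawn keys hashed from human-readable tags, so any single
stage (genotype draw, a party's row sample at iteration T, a batch's column
seed, ...) is reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _key(tags: tuple) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(t).encode("utf-8")) for t in tags)


def substream(master_seed: int, *tags) -> np.random.Generator:
    """A generator for the substream named by ``tags`` under ``master_seed``."""
    seq = np.random.SeedSequence(entropy=int(master_seed), spawn_key=_key(tags))
    return np.random.default_rng(seq)


def subseed(master_seed: int, *tags) -> int:
    """A 31-bit integer seed for the named substream (for handing to others)."""
    return int(substream(master_seed, *tags).integers(0, 2**31 - 1))
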