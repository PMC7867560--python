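"""Seed fan-out: one master seed, named independent substreams.

Every stochastic stage (phantom generation, train/test split, weight
initialisation, epoch shuffling) draws from its own substream so that any
stage is reproducible in isolation and cohorts do not depend on generation
order.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31  # keep derived seeds comfortably in int32 range


def _key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, *names: str | int) -> np.random.Generator:
    """Independent Generator for the substream addressed by `names`."""
    return np.random.default_rng(substream_seed(master_seed, *names))


def substream_seed(master_seed: int, *names: str | int) -> int:
    """Deterministic scalar seed for the substream addressed by `names`."""
    entropy = [int(master_seed) % _MOD]
    entropy += [_key(n) if isinstance(n, str) else int(n) % _MOD for n in names]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % _MOD
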