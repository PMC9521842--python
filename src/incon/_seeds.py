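"""Deterministic random substreams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def spawn_rng(seed: int | None, *tokens) -> np.random.Generator:
    """A generator for the substream named by ``tokens`` under ``seed``.

    The same (seed, tokens) pair always yields the same stream, and
    differently named streams are statistically independent.
    """
    if seed is None:
        return np.random.default_rng()
    entropy = [int(seed)] + [zlib.crc32(str(t).encode("utf-8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
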