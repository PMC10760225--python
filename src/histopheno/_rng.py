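"""Deterministic random sub-streams.

All randomness in the package flows from a single integer seed.  Independent
sub-streams for entities (patients, slides, tiles, stages) are derived by
hashing the entity tokens into a :class:`numpy.random.SeedSequence`, so the
stream for one entity never depends on how many other entities were drawn
before it.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "stream_key"]


def stream_key(*tokens: object) -> int:
    """Stable 63-bit key for a tuple of tokens (order-sensitive)."""
    raw = "\x1f".join(repr(t) for t in tokens).encode()
    digest = hashlib.sha256(raw).digest()
    return int.from_bytes(digest[:8], "little") >> 1


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """Return a generator seeded by ``seed`` and a stable hash of ``tokens``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream_key(*tokens)]))
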