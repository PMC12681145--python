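"""Seed management: one master seed fanned out into named substreams."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _stable_key(name: str) -> int:
    # hash() is salted per interpreter; use a stable digest instead
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The same (seed, name) pair always yields an identical stream, and
    distinct names yield statistically independent streams.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(_stable_key(name),))
    return np.random.Generator(np.random.PCG64(ss))
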