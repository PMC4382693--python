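"""Named RNG substreams.

One user-facing integer seed governs the whole pipeline; each stage draws
from an independent substream keyed by stable string names, so adding a stage
never perturbs another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key(name: str) -> int:
    # stable across processes/versions (unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, *names: object) -> np.random.Generator:
    """Generator for the substream identified by (seed, *names).

    Non-string name parts (replicate indices, sizes) are folded in as their
    repr, so replicate streams are reproducible from (seed, size, rep).
    """
    entropy = [int(seed)] + [_key(str(n)) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


__all__ = ["substream"]
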