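"""Named random substreams derived from one master seed.

Every stochastic stage of the pipeline (pattern placement, noise,
inner-CV shuffling, label permutations) draws from its own substream so
that changing the number of draws in one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _key_to_ints(key: tuple) -> tuple[int, ...]:
    out = []
    for part in key:
        if isinstance(part, (int, np.integer)):
            out.append(int(part) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(part).encode()))
    return tuple(out)


def substream(seed: int, *key) -> np.random.Generator:
    """Generator for the substream named by ``key`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence((int(seed) & 0xFFFFFFFF,) + _key_to_ints(key)))


def spawn_seed(seed: int, *key) -> int:
    """A deterministic 31-bit integer seed for libraries that want one."""
    ss = np.random.SeedSequence((int(seed) & 0xFFFFFFFF,) + _key_to_ints(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
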