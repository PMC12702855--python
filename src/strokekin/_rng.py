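"""Named random substreams derived from one root seed.

Every source of randomness in the pipeline draws from a Generator created
here, so a single integer seed reproduces an entire run bit-for-bit while
keeping the stages statistically independent of each other.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = 0x7FFFFFFF  # keep all derived entropy below 2**31


def stream_seed(root_seed: int, name: str) -> int:
    """Deterministic child seed for the named substream."""
    return (int(root_seed) ^ zlib.crc32(name.encode("utf-8"))) & _MASK


def substream(root_seed: int, *names: str | int) -> np.random.Generator:
    """A Generator seeded from ``root_seed`` and a sequence of stream labels."""
    entropy = [int(root_seed) & _MASK]
    for name in names:
        if isinstance(name, int):
            entropy.append(name & _MASK)
        else:
            entropy.append(zlib.crc32(str(name).encode("utf-8")) & _MASK)
    return np.random.default_rng(np.random.SeedSequence(entropy))
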