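"""Named random substreams derived from one root seed.

Every stochastic stage (world generation, permutation test, rotation
starts, ...) draws from its own named substream so that stages are
individually reproducible and adding draws to one stage never perturbs
another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of root ``seed``.

    The stream key is a CRC32 of the name, so substreams are stable across
    sessions and independent of call order.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
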