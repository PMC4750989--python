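"""Named substreams derived from a single master seed.

Every random draw in the package flows from one master integer seed through
:func:`substream`, so any component (a metacommunity, a single local
community, one stochastic trajectory) can be regenerated in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag)
    return zlib.crc32(str(tag).encode("utf8"))


def substream(seed: int, *tags) -> np.random.Generator:
    """Return a Generator for the substream identified by ``tags``.

    Tags may be strings (hashed stably via CRC32) or integers (used as-is),
    e.g. ``substream(seed, "lc", 17)`` for the 17th local community.
    """
    key = tuple(_tag_to_int(t) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
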