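"""Named random substreams derived from one root seed.

Every stochastic stage draws from its own substream so that adding or
reordering a stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return a generator for the substream ``name`` under ``root_seed``.

    The substream key is a CRC32 of the name, so the mapping is stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0xFFFFFFFF, key]))
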