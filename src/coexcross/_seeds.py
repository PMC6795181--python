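"""Named random substreams derived from one root seed.

Every stochastic stage draws from its own substream so that adding or
reordering stages never perturbs another stage's randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _key_part(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0x7FFFFFFF
    return zlib.crc32(str(part).encode("utf-8"))


def substream_seed(root_seed: int, *key) -> np.random.SeedSequence:
    """Seed sequence for the substream named by ``key`` under ``root_seed``."""
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF] + [_key_part(k) for k in key])


def substream(root_seed: int, *key) -> np.random.Generator:
    """Generator for the substream named by ``key`` under ``root_seed``."""
    return np.random.default_rng(substream_seed(root_seed, *key))
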