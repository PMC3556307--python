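"""Named sub-seed scheme.

One user-facing seed fans out to per-stage streams keyed by a stable
string, so any stage can be re-run in isolation and reproduce exactly
the randomness it saw inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def stage_seed(seed: int, name: str) -> int:
    """Derive a deterministic child seed (< 2^31) for a named stage."""
    return (int(seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % _MOD


def stage_rng(seed: int, name: str) -> np.random.Generator:
    """A numpy Generator dedicated to one named stage."""
    return np.random.default_rng(stage_seed(seed, name))
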