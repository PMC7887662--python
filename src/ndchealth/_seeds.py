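"""Per-stage seed substreams.

A single global seed is expanded into independent substreams keyed by stage
name, so adding or reordering pipeline stages never shifts the randomness of
another stage. Stage keys are hashed with a stable (non-salted) scheme.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic 31-bit seed for a named pipeline stage."""
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(global_seed), key])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    """A numpy Generator seeded from the named substream."""
    return np.random.default_rng(stage_seed(global_seed, stage))
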