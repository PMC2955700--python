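"""Deterministic seed derivation for the multi-stage pipeline.

Every stage (per-component layout, MDS, annealing, force guards) draws its
randomness from a child seed derived from the single user-facing seed, so an
identical seed reproduces the whole pipeline bit for bit while stages stay
statistically independent.
"""

from __future__ import annotations

import numpy as np

# spawn-key namespaces; component k uses (_FR, k)
FR_STAGE = 0
MDS_STAGE = 1
ANNEAL_STAGE = 2
INIT_STAGE = 3
GUARD_STAGE = 4


def derived_seed(seed: int, *key: int) -> int:
    """A reproducible child seed (< 2**31) for stage ``key`` of pipeline ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
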