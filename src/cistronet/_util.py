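"""Shared helpers: deterministic sub-seeding and small validators."""

from __future__ import annotations

import numpy as np

# fixed offsets so each pipeline stage draws from an independent stream
STAGE_OFFSETS = {
    "genome": 11,
    "annotations": 23,
    "expression": 37,
    "promoters": 53,
    "training": 61,
    "cv": 71,
    "mi_null": 83,
    "motif": 97,
    "shuffle": 113,
    "qvalue": 127,
}

_MOD = 2**31 - 1


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from one master seed.

    Uses SeedSequence spawning keyed by a fixed per-stage offset so that
    regenerating one stage in isolation reproduces the full-run stream.
    """
    offset = STAGE_OFFSETS[stage]
    ss = np.random.SeedSequence([int(master_seed) % _MOD, offset])
    return int(ss.generate_state(1)[0] % _MOD)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))
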