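"""Seed management.

One master seed drives the whole pipeline.  Each stage draws from its own
child stream, derived with :class:`numpy.random.SeedSequence` spawn keys, so
re-running a single stage with the same master seed reproduces it exactly and
stages never share a stream.
"""
from __future__ import annotations

import numpy as np

#: fixed stage -> spawn-key registry; order is part of the reproducibility
#: contract and must never be reshuffled.
STAGE_KEYS = {
    "covariates": 0,
    "outcomes": 1,
    "missingness": 2,
    "imputation": 3,
    "bootstrap": 4,
    "folds": 5,
    "pipeline": 6,
    "calibration": 7,
}


def stage_rng(seed: int, stage: str, child: int = 0) -> np.random.Generator:
    """Return the generator for ``stage`` (and optional chain index ``child``)."""
    if stage not in STAGE_KEYS:
        raise KeyError(f"unknown rng stage {stage!r}; known: {sorted(STAGE_KEYS)}")
    ss = np.random.SeedSequence(int(seed), spawn_key=(STAGE_KEYS[stage], int(child)))
    return np.random.default_rng(ss)


def child_seed(seed: int, stage: str, child: int = 0) -> int:
    """A plain integer seed (< 2**31) derived from the stage stream."""
    return int(stage_rng(seed, stage, child).integers(0, 2**31 - 1))
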