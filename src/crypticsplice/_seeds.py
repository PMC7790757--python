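"""Deterministic random-stream derivation.

A single user-facing integer seed drives every stochastic stage of the
pipeline (genome construction, expression levels, cohort counts, read
simulation, resampling).  Each stage gets an independent substream derived
via :class:`numpy.random.SeedSequence` with a fixed ``spawn_key``, so adding
a stage or changing how often one stage draws never perturbs the others.
"""

from __future__ import annotations

import numpy as np

_STAGES = {
    "genome": 0,
    "expression": 1,
    "cohort": 2,
    "reads": 3,
    "resample": 4,
    "noise": 5,
}


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Return the generator for one named stage of a seeded run.

    Parameters
    ----------
    seed : global integer seed of the run.
    stage : one of ``genome, expression, cohort, reads, resample, noise``.
    index : optional sub-index (e.g. a sample number) for per-item streams.
    """
    try:
        key = _STAGES[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(_STAGES)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(index)))
    return np.random.default_rng(ss)


def child_seed(seed: int, stage: str, index: int = 0) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    return int(stage_rng(seed, stage, index).integers(2**31))
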