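"""Seed fan-out: one global seed, independent named substreams per pipeline stage."""

from __future__ import annotations

import numpy as np

# Stable stage registry; order is part of the reproducibility contract.
_STAGES = ("specs", "render", "dataset", "split", "augment", "init", "shuffle", "runs")


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed (< 2**31) from a global seed.

    Changing one stage's stream never shifts another's: each stage hashes
    (global_seed, stage index) through an independent ``SeedSequence``.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; known stages: {_STAGES}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    """A ``numpy.random.Generator`` bound to one stage's substream."""
    return np.random.default_rng(derive_seed(global_seed, stage))
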