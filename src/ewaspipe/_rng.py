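"""Deterministic RNG stream derivation.

Every simulator derives its generator from the master seed via a fixed
per-operation spawn key, so adding a new simulation never shifts the draws
of an existing one.  Key table is append-only.
"""

from __future__ import annotations

import numpy as np

# Append-only: never renumber.
_OP_KEYS = {
    "cohort": 1,
    "smoking_phenotype": 2,
    "coverage": 3,
    "genotypes": 4,
    "elastic_net_folds": 5,
    "pipeline": 6,
    "cohort_individuals": 7,
}


def rng_for(seed: int, operation: str) -> np.random.Generator:
    """Return the dedicated Generator for *operation* under *seed*."""
    try:
        key = _OP_KEYS[operation]
    except KeyError:  # pragma: no cover - programming error
        raise KeyError(f"unknown RNG operation {operation!r}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
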