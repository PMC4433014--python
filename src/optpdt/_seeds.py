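"""Deterministic RNG stream derivation.

Every stochastic component derives its generator from a user seed plus a
string label, so results are reproducible regardless of execution order or
worker count.
"""
from __future__ import annotations

import hashlib

import numpy as np


def derive_seed_sequence(seed: int, *labels: object) -> np.random.SeedSequence:
    """Build a SeedSequence from a base seed and arbitrary hashable labels.

    Labels are hashed with SHA-256 so the mapping is stable across Python
    processes (unlike ``hash()``).
    """
    words = [int(seed) & 0xFFFFFFFF]
    for label in labels:
        digest = hashlib.sha256(repr(label).encode()).digest()
        words.append(int.from_bytes(digest[:4], "little"))
        words.append(int.from_bytes(digest[4:8], "little"))
    return np.random.SeedSequence(words)


def derive_rng(seed: int, *labels: object) -> np.random.Generator:
    """A numpy Generator seeded from (seed, *labels)."""
    return np.random.default_rng(derive_seed_sequence(seed, *labels))
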