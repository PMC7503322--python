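"""Deterministic, collision-resistant seed derivation.

Every source of randomness in the package is a ``numpy`` generator seeded
through :func:`derive_seed`, which hashes ``(root_seed, participant, label)``
so that distinct participants and distinct streams (trial timeline, yoking,
grid layout, agent behaviour, ...) are statistically independent and each is
individually reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "stream_rng"]


def derive_seed(root_seed: int, participant_index: int, label: str) -> int:
    """Derive a sub-seed (< 2**31) for one participant and one named stream."""
    if root_seed < 0:
        raise ValueError("root_seed must be non-negative")
    key = f"{root_seed}|{participant_index}|{label}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def stream_rng(root_seed: int, participant_index: int, label: str) -> np.random.Generator:
    """Generator for one (participant, stream) pair."""
    return np.random.default_rng(derive_seed(root_seed, participant_index, label))
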