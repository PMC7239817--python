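"""Deterministic seed fan-out.

A single master seed is expanded into independent per-stage streams by
hashing ``(master_seed, label)`` with SHA-256, so adding or reordering
stages never perturbs the streams of the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, label: str) -> int:
    """Derive a stable 64-bit child seed from a master seed and a label."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:8], "little")


def child_rng(master_seed: int, label: str) -> np.random.Generator:
    """Return a ``numpy`` Generator seeded from ``(master_seed, label)``."""
    return np.random.default_rng(child_seed(master_seed, label))
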