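"""Deterministic child-stream derivation from a master seed.

Every stochastic component draws from its own named child stream so that
adding a new generator never perturbs the draws of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(master_seed: int, *labels: str | int) -> int:
    """Derive a stable 31-bit child seed from a master seed and labels."""
    key = ":".join([str(int(master_seed))] + [str(l) for l in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def child_rng(master_seed: int, *labels: str | int) -> np.random.Generator:
    """A numpy Generator seeded from a named child stream."""
    return np.random.default_rng(child_seed(master_seed, *labels))
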