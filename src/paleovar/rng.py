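"""Deterministic named random substreams.

Every stage of the pipeline draws from its own child stream derived from a
single master seed plus a human-readable name, so any stage can be re-run in
isolation and reproduce its output regardless of what the other stages drew.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "substream"]


def child_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from ``master_seed`` and ``name``."""
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A numpy Generator seeded from the named substream."""
    return np.random.default_rng(child_seed(master_seed, name))
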