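"""Deterministic seed plumbing.

All randomness in the package flows from one root seed split into named
per-stage streams, so any stage can be re-run in isolation and the whole
pipeline is reproducible bit-for-bit from the root seed alone.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng", "stable_u32"]


def stable_u32(name: str) -> int:
    """A stable 32-bit integer derived from a string (independent of PYTHONHASHSEED)."""
    digest = hashlib.blake2b(name.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def child_seed(root_seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from a root seed."""
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, stable_u32(name)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def child_rng(root_seed: int, name: str) -> np.random.Generator:
    """A Generator for the named stream of ``root_seed``."""
    return np.random.default_rng(child_seed(root_seed, name))
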