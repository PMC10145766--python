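"""Deterministic child-seed derivation.

Every stage of the pipeline consumes a child seed derived from the master
seed and a short stage label, so reruns with one master seed reproduce all
random decisions while stages stay statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(master_seed: int, label: str) -> int:
    """A seed < 2**31, a pure function of (master_seed, label)."""
    key = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, label))
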