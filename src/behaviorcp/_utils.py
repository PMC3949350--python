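"""Small shared helpers: stable hashing, seed derivation, logistic."""

from __future__ import annotations

import hashlib

import numpy as np

_SEED_MOD = 2**31


def stable_hash(text: str) -> int:
    """Deterministic 32-bit hash of a string (stable across processes)."""
    digest = hashlib.blake2s(text.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a stage/child seed < 2**31 from a master seed and a label.

    Stable across runs and platforms, unlike ``hash()``.
    """
    digest = hashlib.blake2s(
        f"{int(master_seed)}:{label}".encode("utf-8"), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % _SEED_MOD


def sigmoid(x):
    """Numerically safe logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out
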