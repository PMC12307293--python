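"""Shared helpers: seeding, normalization, validation."""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("tmenet")


class ConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


class GenerationError(RuntimeError):
    """Raised when a stochastic generator exhausts its attempt budget."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from a global seed.

    Hash-based so that stages never share streams; result is always a
    valid 31-bit seed.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


def as_dense(X) -> np.ndarray:
    """Return a dense float ndarray view of a (possibly sparse) matrix."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def lognorm(X, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalize rows to ``target_sum`` and log1p.

    The standard counts-per-10k + natural-log transform used throughout
    the single-cell stages. Rows with zero total are left at zero.
    """
    X = as_dense(X)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(X / totals * target_sum)


def check_positive(name: str, value) -> None:
    if not value > 0:
        raise ConfigError(f"{name} must be positive, got {value!r}")
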