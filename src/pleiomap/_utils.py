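"""Shared helpers: seeded RNG streams, validation, empirical p-values."""

from __future__ import annotations

import numpy as np


def rng_stream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from a master seed.

    Each pipeline stage gets an independent stream so that changing the
    number of draws in one stage never perturbs another.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(hash_label(stage),))
    return np.random.default_rng(ss)


def hash_label(label: str) -> int:
    # stable across processes (unlike builtin hash)
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


def empirical_p(observed: float, null: np.ndarray, tail: str = "upper") -> float:
    """Permutation p-value with +1 smoothing; never exactly zero.

    tail: 'upper' counts null >= observed, 'two' counts |null| >= |observed|.
    """
    null = np.asarray(null, dtype=float)
    n = null.size
    if tail == "upper":
        k = int(np.sum(null >= observed))
    elif tail == "lower":
        k = int(np.sum(null <= observed))
    elif tail == "two":
        k = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1.0 + k) / (n + 1.0)


def check_symmetric(W: np.ndarray, tol: float = 1e-12, name: str = "matrix") -> None:
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name} must be square, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=tol, rtol=0.0):
        raise ValueError(f"{name} is not symmetric within {tol}")


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def upper_triangle(W: np.ndarray) -> np.ndarray:
    """Strictly upper-triangular entries as a flat vector."""
    W = np.asarray(W)
    iu = np.triu_indices(W.shape[0], k=1)
    return W[iu]
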