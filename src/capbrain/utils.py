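"""Small shared numerical helpers: seeded RNG trees and Pearson correlations."""

from __future__ import annotations

import numpy as np


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an int, None or SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def rng_children(seed, n: int) -> list[np.random.Generator]:
    """Expand one global seed into ``n`` independent child generators.

    A single :class:`numpy.random.SeedSequence` is spawned ``n`` times, so
    every component of a simulation gets its own stream while the whole
    pipeline stays reproducible from one integer.
    """
    ss = as_seed_sequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between two 1-D vectors; NaN if either is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(ac @ bc / (na * nb))


def pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two (n, m) arrays; NaN for constant columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    na = np.linalg.norm(ac, axis=0)
    nb = np.linalg.norm(bc, axis=0)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", ac, bc) / denom
    r[denom == 0.0] = np.nan
    return r


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between two (n, m) arrays."""
    return pearson_columns(np.asarray(a).T, np.asarray(b).T)
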