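"""Core geometric statistics on a reduced (contrastively specified) inventory.

An inventory projected onto one irreducible feature subset is a set of s
distinct vertices of the k-dimensional binary hypercube.  Three raw
quantities live here:

* the segment distance d(p_i, p_j) = ½ Σ_k |p_{i,k} − p_{j,k}| (Hamming),
* N_mp = number of unordered segment pairs at distance exactly 1 (the
  "oppositions", i.e. occupied hypercube edges),
* N_im = Σ_k |Σ_i p_{i,k}|, the total imbalance across dimensions,

plus the economy score Econ = (s − (p+1)) / (2^p − (p+1)), which measures how
fully an inventory occupies the 2^p cells its p contrastive dimensions
define (0 at the sparsest possible inventory for p dimensions, 1 when the
hypercube is saturated).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "segment_distance",
    "count_minimal_pairs",
    "imbalance_sum",
    "economy_score",
    "validate_reduced",
    "EconomyDomainError",
]


class EconomyDomainError(ValueError):
    """An (s, p) pair outside the feasible region — signals corrupt input."""


def segment_distance(a, b) -> int:
    """Hamming distance between two ±1 feature vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def _pairwise_distances(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.int32)
    k = m.shape[1]
    # for ±1 vectors, d = (k − a·b) / 2
    return (k - m @ m.T) // 2


def count_minimal_pairs(matrix: np.ndarray) -> int:
    """N_mp: unordered segment pairs differing on exactly one dimension."""
    d = _pairwise_distances(matrix)
    return int((np.triu(d == 1, 1)).sum())


def imbalance_sum(matrix: np.ndarray) -> int:
    """N_im: sum over dimensions of the absolute column sums."""
    m = np.asarray(matrix, dtype=np.int64)
    return int(np.abs(m.sum(axis=0)).sum())


def economy_score(s: int, p: float) -> float | None:
    """Econ = (s − (p+1)) / (2^p − (p+1)).

    ``p`` is the median contrastive dimension of the inventory and may be
    half-integral (median of an even number of variant representations);
    2^p is then real exponentiation.  Returns None (score undefined) when
    p = 1, where the denominator vanishes — a two-segment inventory's
    economy carries no information.  Values outside [0, 1] cannot arise
    from a real (s, p) pair and raise :class:`EconomyDomainError`.
    """
    if s < 2:
        raise EconomyDomainError(f"need s >= 2, got s={s}")
    if p < 1:
        raise EconomyDomainError(f"need p >= 1, got p={p}")
    if float(p) == 1.0:
        return None
    if s > 2.0**p + 1e-9:
        raise EconomyDomainError(f"impossible inventory: s={s} > 2^p for p={p}")
    val = (s - (p + 1)) / (2.0**p - (p + 1))
    if val < -1e-12 or val > 1 + 1e-12:
        raise EconomyDomainError(f"Econ={val} outside [0,1] for s={s}, p={p}")
    return float(min(max(val, 0.0), 1.0))


def validate_reduced(matrix: np.ndarray) -> None:
    """Check ReducedInventory invariants: distinct rows, non-constant columns."""
    m = np.asarray(matrix)
    if len(np.unique(m, axis=0)) != m.shape[0]:
        raise ValueError("reduced inventory has duplicate rows")
    if (np.abs(m.sum(axis=0)) == m.shape[0]).any():
        raise ValueError("reduced inventory has a constant column")
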