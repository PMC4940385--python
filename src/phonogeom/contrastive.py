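"""Search for variant representations: irreducible sufficient feature subsets.

A feature subset is *sufficient* for an inventory when projecting the
segment matrix onto it leaves all rows distinct, and *irreducible* when no
single feature can be removed without breaking sufficiency (equivalently, it
is a minimal sufficient subset).  An inventory generally has several such
subsets — its variant representations — and their median size p is the
inventory's number of contrastive dimensions.

Two searches are provided.  The exact search walks the power set bottom-up,
level by level, expanding only insufficient subsets; this finds every
minimal sufficient subset because all proper subsets of a minimal one are
insufficient and therefore stay on the frontier.  The capped search is the
same walk with a fixed upper limit on the frontier: when a level's frontier
exceeds the cap, a uniformly random cap-sized subsample is expanded and the
rest are recorded as skipped; a sufficient set is then admitted only if it
is not a proper superset of any skipped subset (a conservative guard — such
supersets are discarded even though some could in fact be irreducible) and
if removing each single feature breaks sufficiency.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ContrastiveSpec",
    "SpecSet",
    "is_sufficient",
    "find_specs_exact",
    "find_specs_capped",
    "median_dimension",
    "SearchBudgetError",
]


class SearchBudgetError(RuntimeError):
    """Exact search frontier exceeded its budget; use the capped search."""


@dataclass(frozen=True)
class ContrastiveSpec:
    """One irreducible sufficient feature subset (indices into feature order)."""

    feature_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "feature_indices", tuple(sorted(self.feature_indices))
        )

    @property
    def k(self) -> int:
        return len(self.feature_indices)


@dataclass(frozen=True)
class SpecSet:
    """All variant representations found for one inventory.

    ``p`` is the median spec size (real-valued when the median of an
    even-length list straddles two integers); ``exact_flag`` records whether
    the search was exhaustive (no frontier was ever truncated).
    """

    inventory_id: str
    specs: tuple[ContrastiveSpec, ...]
    p: float
    exact_flag: bool
    cap: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("SpecSet needs at least one spec")

    @property
    def n_variants(self) -> int:
        return len(self.specs)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["specs"] = [list(sp.feature_indices) for sp in self.specs]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpecSet":
        d = json.loads(Path(path).read_text())
        d["specs"] = tuple(ContrastiveSpec(tuple(s)) for s in d["specs"])
        return cls(**d)


def _matrix_of(inv) -> np.ndarray:
    return np.asarray(getattr(inv, "matrix", inv), dtype=np.int8)


def _bit_columns(matrix: np.ndarray) -> np.ndarray:
    return (matrix > 0).astype(np.int64)


def _sufficient(bits: np.ndarray, subset: Sequence[int]) -> bool:
    cols = list(subset)
    if not cols:
        return bits.shape[0] < 2
    codes = bits[:, cols] @ (1 << np.arange(len(cols), dtype=np.int64))
    return len(set(codes.tolist())) == bits.shape[0]


def is_sufficient(inv, subset: Sequence[int]) -> bool:
    """True iff projecting onto ``subset`` keeps all segment rows distinct."""
    matrix = _matrix_of(inv)
    if any(j < 0 or j >= matrix.shape[1] for j in subset):
        raise IndexError(f"feature index out of range for K={matrix.shape[1]}")
    return _sufficient(_bit_columns(matrix), subset)


def median_dimension(sizes) -> float:
    """Median spec size; mean of the two middle order statistics when even."""
    if isinstance(sizes, SpecSet):
        sizes = [sp.k for sp in sizes.specs]
    else:
        sizes = [getattr(x, "k", x) for x in sizes]
    if not sizes:
        raise ValueError("median of empty spec list")
    return float(statistics.median(sizes))


def _levelwise_search(
    matrix: np.ndarray,
    cap: int | None,
    rng: np.random.Generator | None,
    strict: bool,
    max_frontier: int,
) -> tuple[list[frozenset[int]], bool]:
    """Shared bottom-up walk.  Returns (specs over pruned indices, truncated)."""
    s, K = matrix.shape
    if len(np.unique(matrix, axis=0)) != s:
        raise ValueError("inventory rows are not distinct; no subset is sufficient")
    # constant columns can never help distinguish: prune (output-preserving)
    colsums = np.abs(matrix.astype(np.int64).sum(axis=0))
    keep = [j for j in range(K) if colsums[j] != s]
    bits = _bit_columns(matrix[:, keep])
    feats = range(len(keep))

    specs: list[frozenset[int]] = []
    skipped: list[frozenset[int]] = []
    sufficient_seen: list[frozenset[int]] = []
    truncated = False
    current: list[frozenset[int]] = [frozenset({f}) for f in feats]
    while current:
        frontier: list[frozenset[int]] = []
        for sub in current:
            if _sufficient(bits, sorted(sub)):
                sufficient_seen.append(sub)
                if not strict and any(sk < sub for sk in skipped):
                    continue
                if all(
                    not _sufficient(bits, sorted(sub - {x})) for x in sub
                ):
                    specs.append(sub)
            else:
                frontier.append(sub)
        if not frontier:
            break
        if cap is not None and len(frontier) > cap:
            assert rng is not None
            order = rng.permutation(len(frontier))
            skipped.extend(frontier[i] for i in order[cap:])
            frontier = [frontier[i] for i in sorted(order[:cap])]
            truncated = True
        elif cap is None and len(frontier) > max_frontier:
            raise SearchBudgetError(
                f"exact search frontier {len(frontier)} exceeds budget "
                f"{max_frontier}; use find_specs_capped"
            )
        nxt = {sub | {f} for sub in frontier for f in feats if f not in sub}
        current = sorted(nxt, key=sorted)
    if not specs and sufficient_seen:
        # pathological truncation: every candidate fell to the skipped-superset
        # guard.  Recover one genuine minimal sufficient subset by greedily
        # shrinking the smallest sufficient set reached (deterministic order).
        start = min(sufficient_seen, key=lambda f: (len(f), sorted(f)))
        sub = set(start)
        for x in sorted(start):
            if x in sub and _sufficient(bits, sorted(sub - {x})):
                sub.discard(x)
        specs.append(frozenset(sub))
    # map pruned indices back to original feature indices
    mapped = [frozenset(keep[j] for j in sub) for sub in specs]
    return mapped, truncated


def _make_specset(
    inv,
    raw_specs: list[frozenset[int]],
    truncated: bool,
    cap: int | None,
    seed: int | None,
) -> SpecSet:
    specs = tuple(
        ContrastiveSpec(tuple(sorted(sub)))
        for sub in sorted(raw_specs, key=lambda f: (len(f), sorted(f)))
    )
    return SpecSet(
        inventory_id=str(getattr(inv, "language_id", "")),
        specs=specs,
        p=median_dimension([sp.k for sp in specs]),
        exact_flag=not truncated,
        cap=cap,
        seed=seed,
    )


def find_specs_exact(inv, max_frontier: int = 500_000) -> SpecSet:
    """All irreducible sufficient feature subsets, by exhaustive level walk.

    Raises :class:`SearchBudgetError` if a level's frontier would exceed
    ``max_frontier`` — intended for small K or small inventories.
    """
    matrix = _matrix_of(inv)
    raw, _ = _levelwise_search(matrix, None, None, strict=False, max_frontier=max_frontier)
    return _make_specset(inv, raw, truncated=False, cap=None, seed=None)


def find_specs_capped(
    inv, cap: int = 1000, seed: int = 0, strict: bool = False
) -> SpecSet:
    """Frontier-capped approximate search (deterministic given ``seed``).

    Equals :func:`find_specs_exact` whenever no frontier was ever truncated
    (``exact_flag`` is then true).  With ``strict=True`` the conservative
    skipped-superset guard is dropped and minimality is established by
    direct single-removal testing alone.  If the guard discards every
    candidate (possible only under very aggressive caps), one minimal
    sufficient subset is recovered by greedy shrinking, so the result is
    never empty; every returned spec is always a member of the exact
    search's output.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    matrix = _matrix_of(inv)
    rng = np.random.default_rng(seed)
    raw, truncated = _levelwise_search(
        matrix, cap, rng, strict=strict, max_frontier=0
    )
    return _make_specset(inv, raw, truncated, cap=cap, seed=seed)
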