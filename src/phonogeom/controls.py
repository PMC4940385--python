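"""Size-matched random control inventories (the null models).

Four families, forming a 2 × 2 design (segment vs feature sampling ×
frequency-matched vs uniform):

* ``segment_freq``    — distinct attested feature combinations drawn with
  probability proportional to their cross-linguistic frequency;
* ``segment_uniform`` — distinct attested combinations, equiprobable;
* ``feature_freq``    — each feature value of each sound an independent
  biased coin with the empirical +1 probability for that feature (the
  result need not be an attested segment);
* ``feature_uniform`` — independent fair coins.

Every control is matched in size (and, for segment controls, in pool) to
one natural inventory of the same subsystem, and then flows through the
identical contrastive → geometry → rank-scoring path as the naturals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featuredb import ComboFrequencies, EncodedInventory

__all__ = [
    "CONTROL_KINDS",
    "ControlSpec",
    "gen_segment_control",
    "gen_feature_control",
    "build_control_database",
]

CONTROL_KINDS = ("segment_freq", "segment_uniform", "feature_freq", "feature_uniform")


@dataclass(frozen=True)
class ControlSpec:
    """What to generate: kind, the natural inventory matched, and the seed."""

    kind: str
    matched_language_id: str
    subsystem: str
    size: int
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in CONTROL_KINDS:
            raise ValueError(f"unknown control kind {self.kind!r}")


def _draw_distinct_combos(
    combos: list[tuple[int, ...]],
    weights: np.ndarray,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Successive weighted draws of distinct combos.

    Duplicates are impossible by construction: each draw renormalizes over
    the not-yet-chosen pool, which yields exactly the distribution of
    reject-and-redraw duplicate handling with fewer RNG consumptions.
    """
    if size > len(combos):
        raise ValueError(
            f"pool of {len(combos)} combos smaller than target size {size}"
        )
    w = np.asarray(weights, dtype=float).copy()
    if (w <= 0).any():
        raise ValueError("combo weights must be positive")
    chosen: list[int] = []
    for _ in range(size):
        p = w / w.sum()
        idx = int(rng.choice(len(combos), p=p))
        chosen.append(idx)
        w[idx] = 0.0
    return np.array([combos[i] for i in chosen], dtype=np.int8)


def gen_segment_control(spec: ControlSpec, pool: ComboFrequencies) -> EncodedInventory:
    """A size-matched random inventory of distinct attested combos.

    ``segment_freq`` draws with probability proportional to each combo's
    cross-linguistic frequency; ``segment_uniform`` equiprobably.  The pool
    must already be restricted to the matched subsystem.
    """
    if spec.kind not in ("segment_freq", "segment_uniform"):
        raise ValueError(f"not a segment-control kind: {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    weights = (
        pool.weights
        if spec.kind == "segment_freq"
        else np.ones(pool.pool_size, dtype=float)
    )
    matrix = _draw_distinct_combos(pool.combos, weights, spec.size, rng)
    return EncodedInventory(
        f"{spec.matched_language_id}|{spec.kind}", spec.subsystem, matrix
    )


def gen_feature_control(
    spec: ControlSpec,
    value_probs: np.ndarray | None,
    n_features: int,
    max_rejects: int = 100_000,
) -> EncodedInventory:
    """A size-matched inventory of independently sampled feature vectors.

    Each coordinate of each sound is an independent biased coin (+1 with the
    given probability); sounds identical to a previously sampled sound are
    rejected and resampled.  ``feature_uniform`` uses probability 0.5
    everywhere (pass ``value_probs=None``).

    Subsystem-conditioned empirical probabilities can be degenerate — e.g.
    every vowel token is [+syllabic], so that coordinate's probability is
    exactly 1 — in which case the coordinate is sampled deterministically
    and only the non-degenerate coordinates bound the number of distinct
    sounds reachable.
    """
    if spec.kind not in ("feature_freq", "feature_uniform"):
        raise ValueError(f"not a feature-control kind: {spec.kind!r}")
    if spec.kind == "feature_uniform":
        probs = np.full(n_features, 0.5)
    else:
        probs = np.asarray(value_probs, dtype=float)
        if probs.shape != (n_features,):
            raise ValueError("value_probs must have one entry per feature")
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("feature probabilities must be in [0, 1]")
    n_free = int(((probs > 0) & (probs < 1)).sum())
    if spec.size > 2**n_free:
        raise ValueError(
            f"size {spec.size} exceeds 2^{n_free} distinct sounds reachable "
            "with the given feature probabilities"
        )
    rng = np.random.default_rng(spec.seed)
    seen: set[tuple[int, ...]] = set()
    rows: list[tuple[int, ...]] = []
    rejects = 0
    while len(rows) < spec.size:
        vec = tuple(np.where(rng.random(n_features) < probs, 1, -1).tolist())
        if vec in seen:
            rejects += 1
            if rejects > max_rejects:
                raise RuntimeError(
                    "feature-control sampling stalled; probabilities too "
                    f"skewed for size {spec.size} on K={n_features}"
                )
            continue
        seen.add(vec)
        rows.append(vec)
    return EncodedInventory(
        f"{spec.matched_language_id}|{spec.kind}",
        spec.subsystem,
        np.array(rows, dtype=np.int8),
    )


def build_control_database(
    naturals: list[EncodedInventory],
    kind: str,
    pool: ComboFrequencies | None = None,
    value_probs: np.ndarray | None = None,
    n_features: int | None = None,
    seed: int = 0,
) -> list[EncodedInventory]:
    """One size-matched control per natural inventory, deterministic in seed.

    Segment kinds need ``pool`` (the subsystem-restricted combo
    frequencies); feature kinds need ``n_features`` and, for
    ``feature_freq``, the subsystem-specific ``value_probs``.
    """
    if kind not in CONTROL_KINDS:
        raise ValueError(f"unknown control kind {kind!r}")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(naturals)) >> 1
    controls: list[EncodedInventory] = []
    for nat, child in zip(naturals, child_seeds):
        spec = ControlSpec(kind, nat.language_id, nat.subsystem, nat.s, int(child))
        if kind.startswith("segment"):
            if pool is None:
                raise ValueError("segment controls need a combo-frequency pool")
            controls.append(gen_segment_control(spec, pool))
        else:
            if n_features is None:
                n_features = nat.n_features
            controls.append(gen_feature_control(spec, value_probs, n_features))
    return controls
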