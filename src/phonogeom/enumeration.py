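"""Attainable-value tables and rank-normalized symmetry scores.

Local and global symmetry are *relative* statistics: an inventory's raw
N_mp is converted into its rank among all values of N_mp attainable by any
geometrically distinct irreducible configuration of the same size s and
dimension k, normalized to [0, 1]; N_im likewise, conditioned additionally
on N_mp and ranked in descending order so that balanced inventories score
high.  Two configurations are geometrically the same when one maps onto the
other by reordering segments, permuting dimensions, or flipping the polarity
of a dimension — exactly the operations that leave N_mp and N_im unchanged.

The tables are built by exhaustive enumeration of s-subsets of the k-cube
when that is feasible, and by seeded rejection sampling of irreducible
configurations otherwise; attested configurations (the variant
representations actually observed) are always unioned in, so every observed
value is rankable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import count_minimal_pairs, economy_score, imbalance_sum

__all__ = [
    "canonical_form",
    "enumerate_geometries",
    "GeometrySample",
    "RankTable",
    "build_rank_tables",
    "loc_score",
    "glob_score",
    "score_inventory",
    "InventoryScores",
]


def canonical_form(matrix: np.ndarray) -> tuple:
    """A hashable key invariant under row order, column permutation, and
    per-column polarity flip; equal keys iff same orbit.

    The key is the lexicographic minimum, over all column orders and sign
    choices, of the sorted row list, found by a staged search: columns are
    chosen one at a time, keeping every partial choice whose sorted prefix
    ties the stage minimum.  Partial states with identical futures (same
    multiset of (prefix row, residual row) pairs over the same unused
    columns) are merged, which keeps the beam small even for highly
    symmetric configurations like the full cube.
    """
    m = np.asarray(matrix, dtype=np.int8)
    if m.ndim != 2:
        raise ValueError("canonical_form expects a 2-D matrix")
    s, k = m.shape
    rows = [tuple(int(v) for v in m[i]) for i in range(s)]
    # state: (used: frozenset, prefix: tuple of per-row tuples, aligned to rows)
    states: list[tuple[frozenset, tuple]] = [(frozenset(), tuple(() for _ in range(s)))]
    best_key: tuple = ()
    for _ in range(k):
        stage_best = None
        stage_states: dict = {}
        for used, prefix in states:
            for j in range(k):
                if j in used:
                    continue
                for sign in (1, -1):
                    newpref = tuple(
                        prefix[i] + (sign * rows[i][j],) for i in range(s)
                    )
                    key = tuple(sorted(newpref))
                    if stage_best is None or key < stage_best:
                        stage_best = key
                        stage_states = {}
                    if key == stage_best:
                        newused = used | {j}
                        unused = sorted(set(range(k)) - newused)
                        sig = (
                            newused,
                            tuple(
                                sorted(
                                    (newpref[i], tuple(rows[i][u] for u in unused))
                                    for i in range(s)
                                )
                            ),
                        )
                        if sig not in stage_states:
                            stage_states[sig] = (newused, newpref)
        states = list(stage_states.values())
        best_key = stage_best  # type: ignore[assignment]
    return best_key


def _codes_to_matrix(codes: Sequence[int], k: int) -> np.ndarray:
    return np.array(
        [[1 if (c >> j) & 1 else -1 for j in range(k)] for c in codes],
        dtype=np.int8,
    )


def _irreducible_codes(codes: Sequence[int], k: int) -> bool:
    """True iff dropping any single dimension merges at least two vertices."""
    n = len(codes)
    for j in range(k):
        mask = ~(1 << j)
        if len({c & mask for c in codes}) == n:
            return False
    return True


@dataclass
class GeometrySample:
    """Canonical irreducible configurations for one (s, k), with provenance."""

    s: int
    k: int
    configs: list[np.ndarray]
    provenance: str


def enumerate_geometries(
    s: int,
    k: int,
    raw_budget: int = 200_000,
    sample_budget: int = 10_000,
    seed: int = 0,
    max_tries: int | None = None,
) -> GeometrySample:
    """Geometrically distinct irreducible s-subsets of the k-cube.

    Exhaustive over all C(2^k, s) subsets when that count is within
    ``raw_budget``; otherwise seeded rejection sampling up to
    ``sample_budget`` distinct configurations.  Irreducibility (every
    dimension necessary to keep the vertices distinct) implies s >= k+1, so
    keys violating that yield an empty sample.
    """
    if k < 1 or s < 2:
        raise ValueError(f"need k >= 1 and s >= 2, got (s={s}, k={k})")
    if s > 2**k:
        raise ValueError(f"impossible: s={s} > 2^k={2 ** k}")
    if s < k + 1:
        return GeometrySample(s, k, [], "none (irreducibility needs s >= k+1)")

    n_raw = math.comb(2**k, s)
    seen: dict = {}
    if n_raw <= raw_budget:
        from itertools import combinations

        for codes in combinations(range(2**k), s):
            if not _irreducible_codes(codes, k):
                continue
            mat = _codes_to_matrix(codes, k)
            key = canonical_form(mat)
            if key not in seen:
                seen[key] = mat
        return GeometrySample(s, k, list(seen.values()), "exhaustive")

    rng = np.random.default_rng(seed)
    if max_tries is None:
        max_tries = 20 * sample_budget
    seen_raw: set = set()
    tries = 0
    while len(seen) < sample_budget and tries < max_tries:
        if len(seen_raw) == n_raw:
            break  # every raw subset has been examined
        tries += 1
        codes = tuple(sorted(rng.choice(2**k, size=s, replace=False).tolist()))
        if codes in seen_raw:
            continue
        seen_raw.add(codes)
        if not _irreducible_codes(codes, k):
            continue
        mat = _codes_to_matrix(codes, k)
        key = canonical_form(mat)
        if key not in seen:
            seen[key] = mat
    return GeometrySample(
        s, k, list(seen.values()), f"sampled(n={len(seen)}, seed={seed})"
    )


@dataclass
class RankTable:
    """Attainable-value lists: N_mp per (s, k), N_im per (s, k, N_mp)."""

    mp_values: dict[tuple[int, int], list[int]] = field(default_factory=dict)
    im_values: dict[tuple[int, int, int], list[int]] = field(default_factory=dict)
    provenance: dict[tuple[int, int], str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mp_values": {f"{s},{k}": v for (s, k), v in self.mp_values.items()},
            "im_values": {
                f"{s},{k},{m}": v for (s, k, m), v in self.im_values.items()
            },
            "provenance": {f"{s},{k}": v for (s, k), v in self.provenance.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RankTable":
        d = json.loads(Path(path).read_text())

        def parse(key: str) -> tuple[int, ...]:
            return tuple(int(x) for x in key.split(","))

        return cls(
            mp_values={parse(key): v for key, v in d["mp_values"].items()},  # type: ignore[misc]
            im_values={parse(key): v for key, v in d["im_values"].items()},  # type: ignore[misc]
            provenance={parse(key): v for key, v in d["provenance"].items()},  # type: ignore[misc]
        )


def build_rank_tables(
    attested: Iterable[np.ndarray],
    raw_budget: int = 200_000,
    sample_budget: int = 10_000,
    seed: int = 0,
    return_pool: bool = False,
):
    """Build attainable-value tables from attested variants plus enumeration.

    ``attested`` is every reduced variant-representation matrix observed in
    the data (natural and control inventories alike); these are pooled,
    deduplicated by canonical form, and unioned with the enumerated or
    sampled configurations for every (s, k) key appearing, so that every
    attested value is rankable even when sampling missed its configuration.

    With ``return_pool=True`` also returns one row per distinct pooled
    configuration: ``(s, k, n_mp, n_im)`` — the population over which the
    three statistics are decorrelated by construction of the ranks.
    """
    by_key: dict[tuple[int, int], dict] = {}
    for mat in attested:
        mat = np.asarray(mat, dtype=np.int8)
        s, k = mat.shape
        by_key.setdefault((s, k), {})[canonical_form(mat)] = mat

    table = RankTable()
    pool: list[tuple[int, int, int, int]] = []
    for (s, k), configs in sorted(by_key.items()):
        sample = enumerate_geometries(
            s,
            k,
            raw_budget=raw_budget,
            sample_budget=sample_budget,
            seed=int(np.random.default_rng([seed, s, k]).integers(2**31)),
        )
        for mat in sample.configs:
            configs.setdefault(canonical_form(mat), mat)
        mp_set: set[int] = set()
        im_by_mp: dict[int, set[int]] = {}
        for mat in configs.values():
            nmp = count_minimal_pairs(mat)
            nim = imbalance_sum(mat)
            mp_set.add(nmp)
            im_by_mp.setdefault(nmp, set()).add(nim)
            pool.append((s, k, nmp, nim))
        table.mp_values[(s, k)] = sorted(mp_set)
        for nmp, ims in im_by_mp.items():
            table.im_values[(s, k, nmp)] = sorted(ims)
        table.provenance[(s, k)] = sample.provenance + " + attested"
    if return_pool:
        return table, pool
    return table


def rank_decorrelation(table: RankTable) -> dict[str, float]:
    """Pearson correlations among Econ, Loc, Glob over the rank tables.

    The rank construction decorrelates the statistics *sequentially*: Loc
    factors out size and economy, Glob additionally factors out Loc.  The
    corresponding populations are therefore the tables' own entries: the
    Econ–Loc correlation is taken over one point per attainable (s, k,
    N_mp) triple (where normalized Loc ranks average ½ within every (s, k)
    stratum by construction), and the two Glob correlations over one point
    per attainable (s, k, N_mp, N_im) quadruple (where Glob ranks average ½
    within every (s, k, N_mp) stratum).  All three vanish up to floating
    point; weighting by configuration counts instead would break this,
    since attainable values are not equally populated.
    """
    from scipy.stats import pearsonr

    e_l: list[tuple[float, float]] = []
    for (s, k), vals in table.mp_values.items():
        for nmp in vals:
            lo = loc_score(nmp, (s, k), table)
            ec = economy_score(s, float(k))
            if lo is not None and ec is not None:
                e_l.append((ec, lo))
    quads: list[tuple[float, float, float]] = []
    for (s, k, nmp), ims in table.im_values.items():
        lo = loc_score(nmp, (s, k), table)
        ec = economy_score(s, float(k))
        for nim in ims:
            gl = glob_score(nim, (s, k, nmp), table)
            if gl is not None and lo is not None and ec is not None:
                quads.append((ec, lo, gl))

    def _r(pairs: list[tuple[float, float]]) -> float:
        a = np.array(pairs)
        return float(pearsonr(a[:, 0], a[:, 1])[0])

    return {
        "econ_loc": _r(e_l),
        "loc_glob": _r([(lo, gl) for _, lo, gl in quads]),
        "econ_glob": _r([(ec, gl) for ec, _, gl in quads]),
    }


def loc_score(
    n_mp: int, key: tuple[int, int], table: RankTable
) -> float | None:
    """Normalized ascending rank of N_mp among the key's attainable values.

    None (omitted) when only one value is attainable — the score would add
    no information beyond size and dimension.
    """
    if key not in table.mp_values:
        raise KeyError(f"no rank table for (s, k)={key}; build tables first")
    vals = table.mp_values[key]
    if len(vals) == 1:
        return None
    try:
        idx = vals.index(n_mp)
    except ValueError:
        raise ValueError(
            f"N_mp={n_mp} not in attainable list for {key}; "
            "tables must be built with this variant attested"
        ) from None
    return idx / (len(vals) - 1)


def glob_score(
    n_im: int, key: tuple[int, int, int], table: RankTable
) -> float | None:
    """Normalized *descending* rank of N_im given (s, k, N_mp).

    Largest attainable imbalance scores 0, smallest (most balanced) scores 1.
    None when only one value is attainable.
    """
    if key not in table.im_values:
        raise KeyError(f"no rank table for (s, k, N_mp)={key}; build tables first")
    vals = table.im_values[key]
    if len(vals) == 1:
        return None
    try:
        idx = vals.index(n_im)
    except ValueError:
        raise ValueError(
            f"N_im={n_im} not in attainable list for {key}"
        ) from None
    return (len(vals) - 1 - idx) / (len(vals) - 1)


@dataclass
class InventoryScores:
    """Econ, Loc, Glob for one inventory (None = omitted, with reason)."""

    inventory_id: str
    subsystem: str
    s: int
    p: float
    n_variants: int
    econ: float | None
    loc: float | None
    glob: float | None
    omit_reasons: dict = field(default_factory=dict)


def _median(vals: list[float]) -> float:
    return float(np.median(np.asarray(vals, dtype=float)))


def score_inventory(specset, inv, table: RankTable) -> InventoryScores:
    """Score one inventory: median over its variant representations.

    Each variant is the inventory projected onto one irreducible feature
    subset; Loc/Glob are computed per variant against that variant's own
    (s, k) attainable-value lists and the medians taken over variants with
    defined scores.  A statistic is omitted entirely when every variant's
    value is determined (single attainable value), or, for Econ, when p = 1.
    """
    matrix = np.asarray(inv.matrix, dtype=np.int8)
    s = matrix.shape[0]
    reasons: dict = {}

    econ = economy_score(s, specset.p)
    if econ is None:
        reasons["econ"] = "p=1"

    locs: list[float] = []
    globs: list[float] = []
    for spec in specset.specs:
        sub = matrix[:, list(spec.feature_indices)]
        k = sub.shape[1]
        nmp = count_minimal_pairs(sub)
        lo = loc_score(nmp, (s, k), table)
        if lo is not None:
            locs.append(lo)
        gl = glob_score(imbalance_sum(sub), (s, k, nmp), table)
        if gl is not None:
            globs.append(gl)
    loc = _median(locs) if locs else None
    if loc is None:
        reasons["loc"] = "single-attainable-value"
    glob = _median(globs) if globs else None
    if glob is None:
        reasons["glob"] = "single-attainable-value"

    return InventoryScores(
        inventory_id=specset.inventory_id,
        subsystem=getattr(inv, "subsystem", ""),
        s=s,
        p=specset.p,
        n_variants=specset.n_variants,
        econ=econ,
        loc=loc,
        glob=glob,
        omit_reasons=reasons,
    )
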