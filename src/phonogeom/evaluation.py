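"""ROC/AUC separation of score distributions, with bootstrap intervals.

The comparison of natural against control inventories is framed as a
detection task: decide whether an inventory is natural from one geometric
score alone.  The AUC is the probability that a randomly chosen member of
the positive group scores higher than one of the negative group, ties
counted half — the rank-sum (Mann–Whitney) formulation, identical to the
trapezoidal area under the ROC curve over all thresholds.  Confidence
intervals are percentile bootstrap, resampling within each group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ScoreSample",
    "ROCResult",
    "auc",
    "bootstrap_auc_ci",
    "summarize",
    "compare_external_set",
    "TABLE1_COMPARISONS",
]


@dataclass
class ScoreSample:
    """Defined (non-omitted) scores for one group and one statistic."""

    label: str
    scores: np.ndarray
    sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise ValueError(f"group {self.label!r}: empty score sample")
        if self.sizes is not None:
            self.sizes = np.asarray(self.sizes, dtype=int)
            if self.sizes.shape != self.scores.shape:
                raise ValueError("sizes must align with scores")


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def _scores(x) -> np.ndarray:
    return np.asarray(getattr(x, "scores", x), dtype=float)


def auc(pos, neg) -> float:
    """P(random pos > random neg), ties ½ (rank-sum formulation)."""
    p, n = _scores(pos), _scores(neg)
    if p.size == 0 or n.size == 0:
        raise ValueError("auc: empty group")
    ranks = rankdata(np.concatenate([p, n]))
    r_pos = ranks[: p.size].sum()
    return float((r_pos - p.size * (p.size + 1) / 2) / (p.size * n.size))


def bootstrap_auc_ci(
    pos, neg, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> ROCResult:
    """Percentile bootstrap interval on the AUC, resampling each group."""
    if n_boot < 1 or not (0 < level < 1):
        raise ValueError("need n_boot >= 1 and 0 < level < 1")
    p, n = _scores(pos), _scores(neg)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = auc(
            p[rng.integers(0, p.size, p.size)],
            n[rng.integers(0, n.size, n.size)],
        )
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return ROCResult(auc(p, n), float(lo), float(hi), n_boot, seed)


#: comparisons reported in the summary: (positive group, negative group).
#: AUC > 0.5 means the positive group scores higher.
TABLE1_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("natural", "segment_freq"),
    ("segment_freq", "segment_uniform"),
    ("feature_freq", "feature_uniform"),
    ("feature_uniform", "segment_uniform"),
)

STATISTICS = ("econ", "loc", "glob")


def summarize(
    scores: pd.DataFrame,
    comparisons: tuple[tuple[str, str], ...] = TABLE1_COMPARISONS,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Group means and pairwise bootstrap AUC intervals, per subsystem.

    ``scores`` is tidy with columns ``subsystem, group, inventory_id, econ,
    loc, glob`` (omitted scores as NaN; they are excluded per statistic,
    not listwise).  Rows of the output are either group means or
    comparisons; comparison rows carry a flag: ``~`` when the interval
    contains 0.5, ``<`` when it lies entirely below 0.5, otherwise ``>``.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for subsystem, sub in scores.groupby("subsystem", sort=True):
        groups = {g: d for g, d in sub.groupby("group")}
        for stat in STATISTICS:
            for g in sorted(groups):
                vals = groups[g][stat].dropna().to_numpy()
                rows.append(
                    {
                        "subsystem": subsystem,
                        "statistic": stat,
                        "kind": "mean",
                        "group": g,
                        "n": vals.size,
                        "value": vals.mean() if vals.size else np.nan,
                    }
                )
            for pos_g, neg_g in comparisons:
                if pos_g not in groups or neg_g not in groups:
                    continue
                p = groups[pos_g][stat].dropna().to_numpy()
                n = groups[neg_g][stat].dropna().to_numpy()
                if p.size == 0 or n.size == 0:
                    continue
                res = bootstrap_auc_ci(
                    p, n, n_boot=n_boot, level=level,
                    seed=int(rng.integers(2**31)),
                )
                flag = (
                    "~"
                    if res.ci_low <= 0.5 <= res.ci_high
                    else ("<" if res.ci_high < 0.5 else ">")
                )
                rows.append(
                    {
                        "subsystem": subsystem,
                        "statistic": stat,
                        "kind": "auc",
                        "group": f"{neg_g} < {pos_g}",
                        "n": p.size + n.size,
                        "value": res.auc,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows)


def compare_external_set(
    external: ScoreSample,
    naturals: ScoreSample,
    n_draws: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> ROCResult:
    """AUC interval of naturals vs an external inventory set, size-matched.

    For each draw, a subsample of natural inventories matching the external
    set's inventory-size multiset is drawn (without replacement within a
    draw) and the AUC of naturals-over-external computed; the interval is
    the percentile range of that AUC distribution.  Both samples must carry
    per-inventory sizes.
    """
    if external.sizes is None or naturals.sizes is None:
        raise ValueError("both samples need per-inventory sizes")
    need = Counter(external.sizes.tolist())
    by_size: dict[int, np.ndarray] = {
        int(sz): np.flatnonzero(naturals.sizes == sz) for sz in need
    }
    for sz, cnt in need.items():
        if by_size[sz].size < cnt:
            raise ValueError(
                f"cannot size-match: need {cnt} natural inventories of size "
                f"{sz}, have {by_size[sz].size}"
            )
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_draws)
    for d in range(n_draws):
        idx: list[int] = []
        for sz, cnt in need.items():
            idx.extend(rng.choice(by_size[sz], size=cnt, replace=False).tolist())
        aucs[d] = auc(naturals.scores[idx], external.scores)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return ROCResult(float(np.median(aucs)), float(lo), float(hi), n_draws, seed)
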