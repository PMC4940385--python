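"""Synthetic multi-language segment databases with known ground truth.

The generator emulates the statistical shape of a large typological segment
database: a binary feature system whose attested combination pool has
Zipf-skewed cross-linguistic frequencies, a realistic right-skewed
inventory-size distribution, a controllable fraction of languages carrying
two transcription labels that share one feature encoding (to exercise the
encodability filter), and — the main acceptance surface — a tunable bias
toward minimal-pair-rich (``beta_loc``) and balanced (``beta_glob``)
geometries.  With both betas at zero, language generation reduces *exactly*
to frequency-proportional segment sampling, i.e. the segment-frequency null
model, so any natural-vs-control separation the pipeline then reports is a
false positive.

The generator targets statistical structure only; it has no articulatory or
acoustic model, and segment labels are opaque.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .featuredb import (
    FeatureSystem,
    LanguageInventory,
    write_feature_table,
    write_inventory_table,
)

__all__ = ["SyntheticConfig", "SyntheticDatabase", "gen_feature_system",
           "gen_language", "gen_database", "write_database", "small_study_config"]


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Defaults mirror the scale of the real database the pipeline targets:
    536 languages coded with 23 binary features in 688 attested
    combinations.  ``size_law`` is a shifted negative binomial clipped to
    [min, max]; ``alias_fraction`` of combos get a second label so that
    roughly ``duplicate_rate`` of languages fail the encodability filter
    when injection succeeds.
    """

    K: int = 23
    pool_size: int = 688
    zipf_exponent: float = 1.0
    n_languages: int = 536
    size_law: dict = field(
        default_factory=lambda: {"r": 2.0, "mu": 25.0, "min": 3, "max": 40}
    )
    beta_loc: float = 0.0
    beta_glob: float = 0.0
    duplicate_rate: float = 0.1
    alias_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size > 2**self.K:
            raise ValueError("pool_size exceeds 2^K")
        if self.zipf_exponent < 0 or self.beta_loc < 0 or self.beta_glob < 0:
            raise ValueError("exponents and betas must be >= 0")
        if not (0 <= self.duplicate_rate <= 1 and 0 <= self.alias_fraction <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.size_law["min"] < 2:
            raise ValueError("minimum inventory size must be >= 2")


def small_study_config(**overrides) -> SyntheticConfig:
    """A reduced-scale configuration used throughout the test experiments.

    8 features, a 120-combo pool, 300 languages with sizes in [3, 20]:
    small enough that the exact subset search and the geometry enumeration
    run in seconds while preserving the skewed-frequency structure.
    """
    base = dict(
        K=8,
        pool_size=120,
        n_languages=300,
        size_law={"r": 2.0, "mu": 10.0, "min": 3, "max": 20},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def _feature_names(K: int) -> tuple[str, ...]:
    # the first three carry the conventional class-defining names so the
    # default subsystem rules (vowel/consonant/stop_affricate) apply
    named = ("syllabic", "sonorant", "continuant")
    return named[:K] + tuple(f"f{i + 1:02d}" for i in range(len(named), K))


@dataclass
class SyntheticDatabase:
    feature_system: FeatureSystem
    inventories: list[LanguageInventory]
    truth: dict


def gen_feature_system(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[FeatureSystem, np.ndarray, np.ndarray, dict[int, str]]:
    """Pool of distinct ±1 combos with labels, Zipf weights, and aliases.

    Returns ``(fs, pool_matrix, weights, aliases)`` where ``pool_matrix``
    rows index the primary labels in order, ``weights`` are the unnormalized
    Zipf weights (rank by draw order), and ``aliases`` maps a combo index to
    its second label when one exists.
    """
    q = rng.uniform(0.2, 0.8, size=cfg.K)
    seen: set[tuple[int, ...]] = set()
    pool: list[tuple[int, ...]] = []
    while len(pool) < cfg.pool_size:
        vec = tuple(np.where(rng.random(cfg.K) < q, 1, -1).tolist())
        if vec not in seen:
            seen.add(vec)
            pool.append(vec)
    weights = (np.arange(cfg.pool_size) + 1.0) ** (-cfg.zipf_exponent)
    width = len(str(cfg.pool_size))
    labels = [f"s{i + 1:0{width}d}" for i in range(cfg.pool_size)]
    table = {lab: vec for lab, vec in zip(labels, pool)}
    n_alias = int(round(cfg.alias_fraction * cfg.pool_size))
    alias_idx = rng.choice(cfg.pool_size, size=n_alias, replace=False)
    aliases: dict[int, str] = {}
    for i in sorted(int(x) for x in alias_idx):
        alias_label = labels[i] + "b"
        table[alias_label] = pool[i]
        aliases[i] = alias_label
    fs = FeatureSystem(_feature_names(cfg.K), table)
    return fs, np.array(pool, dtype=np.int8), weights, aliases


def _draw_size(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    law = cfg.size_law
    r, mu, lo = law["r"], law["mu"], law["min"]
    hi = min(law["max"], cfg.pool_size)
    p = r / (r + max(mu - lo, 0.5))
    return int(np.clip(lo + rng.negative_binomial(r, p), lo, hi))


def gen_language(
    cfg: SyntheticConfig,
    pool_matrix: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    size: int | None = None,
) -> list[int]:
    """Sample one language's combo indices by sequential biased sampling.

    A candidate combo's log-weight is log(Zipf weight) + beta_loc · (new
    minimal pairs it would create) − beta_glob · (increase in total
    imbalance); already-chosen combos are excluded.  With both betas zero
    this is exactly frequency-proportional sampling of distinct combos.
    """
    P, K = pool_matrix.shape
    if size is None:
        size = _draw_size(cfg, rng)
    logw = np.log(weights)
    chosen: list[int] = []
    colsum = np.zeros(K, dtype=np.int64)
    pool64 = pool_matrix.astype(np.int64)
    for _ in range(size):
        score = logw.copy()
        if chosen and (cfg.beta_loc > 0 or cfg.beta_glob > 0):
            chosen_m = pool64[chosen]
            dist = (K - pool64 @ chosen_m.T) // 2
            new_mp = (dist == 1).sum(axis=1)
            d_imb = np.abs(colsum + pool64).sum(axis=1) - np.abs(colsum).sum()
            score = score + cfg.beta_loc * new_mp - cfg.beta_glob * d_imb
        score[chosen] = -np.inf
        p = np.exp(score - score[np.isfinite(score)].max())
        p /= p.sum()
        idx = int(rng.choice(P, p=p))
        chosen.append(idx)
        colsum += pool64[idx]
    return chosen


def gen_database(cfg: SyntheticConfig) -> SyntheticDatabase:
    """Generate the full database; reproducible given ``cfg.seed``.

    The ground-truth log records the config, the pool weights and feature
    probabilities, and exactly which languages received an injected
    duplicate-encoding label pair (these, and only these, must fail the
    whole-inventory encodability filter).
    """
    rng = np.random.default_rng(cfg.seed)
    fs, pool, weights, aliases = gen_feature_system(cfg, rng)
    primary_labels = list(fs.segment_table)[: cfg.pool_size]
    width = len(str(cfg.n_languages))
    inventories: list[LanguageInventory] = []
    duplicated: list[str] = []
    for li in range(cfg.n_languages):
        lang_id = f"L{li + 1:0{width}d}"
        idxs = gen_language(cfg, pool, weights, rng)
        labels = {primary_labels[i] for i in idxs}
        if rng.random() < cfg.duplicate_rate:
            aliased = [i for i in idxs if i in aliases]
            if aliased:
                pick = aliased[int(rng.integers(len(aliased)))]
                labels.add(aliases[pick])
                duplicated.append(lang_id)
        inventories.append(LanguageInventory(lang_id, "whole", frozenset(labels)))
    truth = {
        "config": asdict(cfg),
        "weights": weights.tolist(),
        "aliases": {str(k): v for k, v in aliases.items()},
        "duplicated_language_ids": duplicated,
    }
    return SyntheticDatabase(fs, inventories, truth)


def write_database(db: SyntheticDatabase, outdir: str | Path) -> dict[str, Path]:
    """Write features.tsv + inventories.csv + truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.tsv",
        "inventories": outdir / "inventories.csv",
        "truth": outdir / "truth.json",
    }
    write_feature_table(db.feature_system, paths["features"])
    write_inventory_table(db.inventories, paths["inventories"])
    paths["truth"].write_text(json.dumps(db.truth, indent=1, sort_keys=True))
    return paths
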