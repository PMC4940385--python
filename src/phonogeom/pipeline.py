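"""End-to-end orchestration: encode → search → enumerate → score → compare.

One call runs the whole replication design on a database (real files or the
synthetic generator): per-subsystem encoding and encodability filtering,
variant-representation search for naturals and for every requested control
family, a single rank table pooled over *all* variant representations of
all groups plus fresh enumeration, per-inventory scoring with omission
bookkeeping, and the summary table of group means and bootstrap AUC
intervals.  Everything is deterministic given the config's master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrastive, controls, enumeration, evaluation, featuredb, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every stochastic stage seeds off ``seed``."""

    synthetic: synthetic.SyntheticConfig | None = None
    features_path: str | None = None
    inventories_path: str | None = None
    subsystems: tuple[str, ...] = featuredb.SUBSYSTEMS
    control_kinds: tuple[str, ...] = controls.CONTROL_KINDS
    cap: int = 1000
    raw_budget: int = 200_000
    sample_budget: int = 2000
    n_boot: int = 1000
    boot_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and not (
            self.features_path and self.inventories_path
        ):
            raise ValueError("need either a synthetic config or input paths")


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    summary: pd.DataFrame
    omissions: pd.DataFrame
    rejected: dict[str, list[str]]
    rank_table: enumeration.RankTable
    config: RunConfig
    pool_stats: list = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(outdir / "scores.csv", index=False)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        self.omissions.to_csv(outdir / "omissions.csv", index=False)
        self.rank_table.to_json(outdir / "rank_tables.json")
        cfg = dataclasses.asdict(self.config)
        (outdir / "config.json").write_text(json.dumps(cfg, indent=1, default=str))
        (outdir / "rejected.json").write_text(json.dumps(self.rejected, indent=1))


def _stage_seed(master: int, *tags: int) -> int:
    return int(np.random.default_rng([master, *tags]).integers(2**31))


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    if cfg.synthetic is not None:
        db = synthetic.gen_database(cfg.synthetic)
        fs, wholes = db.feature_system, db.inventories
    else:
        fs = featuredb.parse_feature_table(cfg.features_path)
        wholes = featuredb.parse_inventory_table(cfg.inventories_path)

    rules = featuredb.DEFAULT_SUBSYSTEM_RULES
    specsets: list[tuple[contrastive.SpecSet, featuredb.EncodedInventory, str, str]] = []
    rejected: dict[str, list[str]] = {}

    for si, name in enumerate(cfg.subsystems):
        extracted = [
            featuredb.extract_subsystem(inv, rules[name], fs) for inv in wholes
        ]
        encoded, rej = featuredb.filter_encodable(extracted, fs)
        rejected[name] = rej
        logger.info("subsystem %s: %d encodable, %d rejected", name, len(encoded), len(rej))
        if not encoded:
            continue
        pool = featuredb.combo_frequencies(encoded)

        groups: dict[str, list[featuredb.EncodedInventory]] = {"natural": encoded}
        for ki, kind in enumerate(cfg.control_kinds):
            groups[kind] = controls.build_control_database(
                encoded,
                kind,
                pool=pool,
                value_probs=pool.plus_probs if kind == "feature_freq" else None,
                n_features=fs.n_features,
                seed=_stage_seed(cfg.seed, 1, si, ki),
            )
        for gi, (gname, ginvs) in enumerate(groups.items()):
            for ii, inv in enumerate(ginvs):
                ss = contrastive.find_specs_capped(
                    inv, cap=cfg.cap, seed=_stage_seed(cfg.seed, 2, si, gi, ii)
                )
                specsets.append((ss, inv, name, gname))

    variants = [
        np.asarray(inv.matrix)[:, list(spec.feature_indices)]
        for ss, inv, _, _ in specsets
        for spec in ss.specs
    ]
    table, pool_stats = enumeration.build_rank_tables(
        variants,
        raw_budget=cfg.raw_budget,
        sample_budget=cfg.sample_budget,
        seed=_stage_seed(cfg.seed, 3),
        return_pool=True,
    )

    rows = []
    for ss, inv, subsystem, group in specsets:
        sc = enumeration.score_inventory(ss, inv, table)
        rows.append(
            {
                "subsystem": subsystem,
                "group": group,
                "inventory_id": sc.inventory_id,
                "s": sc.s,
                "p": sc.p,
                "n_variants": sc.n_variants,
                "econ": sc.econ,
                "loc": sc.loc,
                "glob": sc.glob,
            }
        )
    scores = pd.DataFrame(rows)

    omissions = (
        scores.melt(
            id_vars=["subsystem", "group"],
            value_vars=["econ", "loc", "glob"],
            var_name="statistic",
        )
        .assign(omitted=lambda d: d["value"].isna())
        .groupby(["subsystem", "group", "statistic"], sort=True)["omitted"]
        .sum()
        .reset_index(name="n_omitted")
    )

    summary = evaluation.summarize(
        scores,
        n_boot=cfg.n_boot,
        level=cfg.boot_level,
        seed=_stage_seed(cfg.seed, 4),
    )

    result = PipelineResult(
        scores=scores,
        summary=summary,
        omissions=omissions,
        rejected=rejected,
        rank_table=table,
        config=cfg,
        pool_stats=pool_stats,
    )
    if outdir is not None:
        result.write(outdir)
    return result
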