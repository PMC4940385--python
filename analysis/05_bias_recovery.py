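#!/usr/bin/env python
"""Parameter recovery: does natural-vs-control AUC track the generation bias?

Re-generates the synthetic database with an increasing minimal-pair bias
(beta_loc in {0, 1, 2}) and runs the natural-vs-frequency-matched-segment
comparison each time.  The Loc AUC must rise monotonically from ~0.5: the
pipeline neither invents structure in unbiased data nor misses structure
that was deliberately generated.
"""

from pathlib import Path

import pandas as pd

import phonogeom as pg

OUT = Path("results/bias_recovery.csv")
SEED = 11
PIPE_SEED = 5


def main() -> None:
    rows = []
    for beta in (0.0, 1.0, 2.0):
        cfg = pg.RunConfig(
            synthetic=pg.small_study_config(seed=SEED, beta_loc=beta),
            subsystems=("whole",),
            control_kinds=("segment_freq",),
            cap=2000,
            sample_budget=300,
            n_boot=500,
            seed=PIPE_SEED,
        )
        res = pg.run_pipeline(cfg)
        aucs = res.summary[res.summary.kind == "auc"].set_index("statistic")
        for stat in ("econ", "loc", "glob"):
            r = aucs.loc[stat]
            rows.append({"beta_loc": beta, "statistic": stat, "auc": r.value,
                         "ci_low": r.ci_low, "ci_high": r.ci_high})
        print(f"beta_loc={beta}: " + "  ".join(
            f"{s}={aucs.loc[s].value:.3f}" for s in ("econ", "loc", "glob")))
    df = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT, index=False)
    loc = df[df.statistic == "loc"].sort_values("beta_loc").auc.tolist()
    assert loc == sorted(loc), "Loc AUC should rise with the generation bias"
    print(f"Loc AUC rises {loc[0]:.3f} -> {loc[-1]:.3f} with the bias; wrote {OUT}")


if __name__ == "__main__":
    main()
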