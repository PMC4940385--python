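#!/usr/bin/env python
"""Encode the database per subsystem and apply the encodability filter.

Reads the tables written by 01_simulate_database.py, extracts the whole,
consonant, stop/affricate and vowel subsystems with the default feature
predicates, drops languages whose subsystem contains two segments with one
feature encoding, and reports the per-subsystem survivor counts (the filter
is independent per subsystem, so the counts differ).
"""

import json
from pathlib import Path

import phonogeom as pg

IN = Path("results/synthetic")
OUT = Path("results/encoded")


def main() -> None:
    fs = pg.parse_feature_table(IN / "features.tsv")
    wholes = pg.parse_inventory_table(IN / "inventories.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    print(f"{len(wholes)} languages loaded")
    for name, rule in pg.DEFAULT_SUBSYSTEM_RULES.items():
        extracted = [pg.extract_subsystem(inv, rule, fs) for inv in wholes]
        encoded, rejected = pg.filter_encodable(extracted, fs)
        payload = [
            {"language_id": e.language_id, "subsystem": e.subsystem,
             "matrix": e.matrix.tolist()}
            for e in encoded
        ]
        (OUT / f"{name}.json").write_text(json.dumps(payload))
        print(f"{name}: {len(encoded)} encodable, {len(rejected)} rejected "
              f"(not expressible in the feature system)")


if __name__ == "__main__":
    main()
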