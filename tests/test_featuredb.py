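import numpy as np
import pytest

import phonogeom as pg
from phonogeom.featuredb import FeatureTableError


@pytest.fixture
def tiny_fs():
    return pg.FeatureSystem(
        ("syllabic", "voice"),
        {
            "a": (1, 1),
            "i": (1, -1),
            "b": (-1, 1),
            "p": (-1, -1),
            "p2": (-1, -1),  # alias: same encoding as p
        },
    )


class TestParseFeatureTable:
    def test_smallest_valid_table(self, tmp_path):
        f = tmp_path / "f.tsv"
        f.write_text("segment\tnasal\na\t+\nb\t-\n")
        fs = pg.parse_feature_table(f)
        assert fs.feature_names == ("nasal",)
        assert fs.segment_table == {"a": (1,), "b": (-1,)}

    def test_unknown_symbol_names_the_cell(self, tmp_path):
        f = tmp_path / "f.tsv"
        f.write_text("segment\tnasal\tvoice\na\t+\t0\n")
        with pytest.raises(FeatureTableError, match="'0'.*'a'.*voice"):
            pg.parse_feature_table(f)

    def test_duplicate_label_rejected(self, tmp_path):
        f = tmp_path / "f.csv"
        f.write_text("segment,nasal\na,+\na,-\n")
        with pytest.raises(FeatureTableError, match="duplicate segment label"):
            pg.parse_feature_table(f)

    def test_roundtrip_large_synthetic_table(self, tmp_path):
        # a database-scale table: 23 features, >1000 labels incl. aliases
        cfg = pg.SyntheticConfig(seed=3, n_languages=1)
        db = pg.gen_database(cfg)
        path = tmp_path / "features.tsv"
        pg.write_feature_table(db.feature_system, path)
        fs2 = pg.parse_feature_table(path)
        assert fs2.feature_names == db.feature_system.feature_names
        assert fs2.segment_table == db.feature_system.segment_table
        assert fs2.n_features == 23
        assert len({v for v in fs2.segment_table.values()}) == 688


class TestExtractSubsystem:
    def test_empty_conjunction_is_identity(self, tiny_fs):
        inv = pg.LanguageInventory("L1", "whole", frozenset({"a", "p", "b"}))
        out = pg.extract_subsystem(inv, pg.SubsystemRule("whole", ()), tiny_fs)
        assert out.segment_labels == inv.segment_labels

    def test_direct_filter(self, tiny_fs):
        inv = pg.LanguageInventory("L1", "whole", frozenset({"a", "i", "p", "b"}))
        vowels = pg.extract_subsystem(
            inv, pg.SubsystemRule("vowel", (("syllabic", 1),)), tiny_fs
        )
        assert vowels.segment_labels == {"a", "i"}
        assert vowels.subsystem == "vowel"

    def test_rule_and_complement_partition(self, tiny_fs):
        inv = pg.LanguageInventory("L1", "whole", frozenset({"a", "i", "p", "b"}))
        v = pg.extract_subsystem(
            inv, pg.SubsystemRule("vowel", (("syllabic", 1),)), tiny_fs
        )
        c = pg.extract_subsystem(
            inv, pg.SubsystemRule("consonant", (("syllabic", -1),)), tiny_fs
        )
        assert v.segment_labels | c.segment_labels == inv.segment_labels
        assert not v.segment_labels & c.segment_labels

    def test_unknown_feature_rejected(self, tiny_fs):
        inv = pg.LanguageInventory("L1", "whole", frozenset({"a"}))
        with pytest.raises(FeatureTableError, match="unknown feature"):
            pg.extract_subsystem(
                inv, pg.SubsystemRule("x", (("nope", 1),)), tiny_fs
            )


class TestFilterEncodable:
    def test_distinct_vectors_kept(self, tiny_fs):
        inv = pg.LanguageInventory("L1", "whole", frozenset({"a", "i", "p"}))
        enc, rej = pg.filter_encodable([inv], tiny_fs)
        assert rej == [] and enc[0].s == 3

    def test_shared_encoding_rejected(self, tiny_fs):
        inv = pg.LanguageInventory("L1", "whole", frozenset({"a", "p", "p2"}))
        enc, rej = pg.filter_encodable([inv], tiny_fs)
        assert enc == [] and rej == ["L1"]

    def test_idempotent_and_rows_distinct(self, tiny_fs):
        invs = [
            pg.LanguageInventory("L1", "whole", frozenset({"a", "i", "b"})),
            pg.LanguageInventory("L2", "whole", frozenset({"p", "p2"})),
        ]
        enc, rej = pg.filter_encodable(invs, tiny_fs)
        assert rej == ["L2"]
        for e in enc:
            assert len(np.unique(e.matrix, axis=0)) == e.s

    def test_injected_duplicates_are_exactly_the_rejections(self):
        cfg = pg.small_study_config(seed=7, duplicate_rate=0.15)
        db = pg.gen_database(cfg)
        _, rej = pg.filter_encodable(db.inventories, db.feature_system)
        assert set(rej) == set(db.truth["duplicated_language_ids"])
        assert len(rej) > 0


class TestComboFrequencies:
    def test_language_containment_counts(self, encoded):
        m1 = np.array([[1, 1], [1, -1]], dtype=np.int8)
        m2 = np.array([[1, 1], [-1, -1]], dtype=np.int8)
        cf = pg.combo_frequencies([encoded(m1, "L1"), encoded(m2, "L2")])
        assert cf.counts[(1, 1)] == 2
        assert cf.counts[(1, -1)] == 1
        # counts sum = sum over languages of distinct combos
        assert sum(cf.counts.values()) == 4

    def test_per_feature_plus_probability(self, encoded):
        cf = pg.combo_frequencies([encoded(np.array([[1], [-1]], dtype=np.int8))])
        assert cf.plus_probs[0] == pytest.approx(0.5)

    def test_empirical_ranks_follow_generator_weights(self):
        db = pg.gen_database(pg.small_study_config(seed=2))
        enc, _ = pg.filter_encodable(db.inventories, db.feature_system)
        cf = pg.combo_frequencies(enc)
        labels = list(db.feature_system.segment_table)
        weights = db.truth["weights"]
        w, c = [], []
        for i in range(120):
            combo = db.feature_system.segment_table[labels[i]]
            w.append(weights[i])
            c.append(cf.counts.get(combo, 0))
        from scipy.stats import spearmanr

        rho = spearmanr(w, c).statistic
        assert rho > 0.5
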