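import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phonogeom as pg
from phonogeom.evaluation import ScoreSample


def brute_force_auc(pos, neg):
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        if p > n:
            wins += 1
        elif p == n:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAUC:
    def test_all_ties_is_half(self):
        assert pg.auc([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_full_separation_is_one(self):
        assert pg.auc([3, 4, 5], [0, 1, 2]) == 1.0

    def test_worked_example(self):
        assert pg.auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pg.auc([], [1.0])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=50),
        st.lists(st.integers(0, 10), min_size=1, max_size=50),
    )
    def test_equals_brute_force_pair_count(self, pos, neg):
        assert pg.auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1, width=32), min_size=1, max_size=30),
        st.lists(st.floats(0, 1, width=32), min_size=1, max_size=30),
    )
    def test_complement_symmetry(self, pos, neg):
        assert pg.auc(pos, neg) + pg.auc(neg, pos) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 40)
        base = pg.auc(pos, neg)
        for f in (np.exp, np.tanh, lambda x: 3 * x + 7):
            assert pg.auc(f(pos), f(neg)) == pytest.approx(base)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.normal(0.5, 1, 30), rng.normal(0, 1, 30)
        a = pg.bootstrap_auc_ci(pos, neg, n_boot=200, seed=7)
        b = pg.bootstrap_auc_ci(pos, neg, n_boot=200, seed=7)
        assert a == b

    def test_separated_samples_interval_at_one(self):
        pos = np.linspace(10, 11, 300)
        neg = np.linspace(0, 1, 300)
        res = pg.bootstrap_auc_ci(pos, neg, n_boot=100, seed=0)
        assert res.ci_low == res.ci_high == res.auc == 1.0

    def test_null_coverage(self):
        # AUC interval should cover 0.5 for ~95% of same-distribution pairs
        rng = np.random.default_rng(3)
        covered = 0
        n_rep = 60
        for _ in range(n_rep):
            pos, neg = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
            res = pg.bootstrap_auc_ci(
                pos, neg, n_boot=200, seed=int(rng.integers(2**31))
            )
            covered += res.ci_low <= 0.5 <= res.ci_high
        assert covered / n_rep > 0.85


class TestSummarize:
    @pytest.fixture
    def scores(self):
        rng = np.random.default_rng(5)
        rows = []
        for group, shift in [("natural", 0.3), ("segment_freq", 0.0)]:
            for i in range(60):
                rows.append(
                    {
                        "subsystem": "whole",
                        "group": group,
                        "inventory_id": f"L{i}",
                        "econ": rng.random(),
                        "loc": min(rng.random() + shift, 1.0),
                        "glob": np.nan if i % 5 == 0 else rng.random(),
                    }
                )
        return pd.DataFrame(rows)

    def test_single_group_means_only(self, scores):
        out = pg.summarize(scores[scores.group == "natural"], n_boot=50, seed=0)
        assert (out["kind"] == "mean").all()

    def test_biased_naturals_auc_above_half(self, scores):
        out = pg.summarize(scores, n_boot=100, seed=0)
        row = out[(out.kind == "auc") & (out.statistic == "loc")].iloc[0]
        assert row.value > 0.5
        assert row.ci_low <= row.value <= row.ci_high

    def test_omitted_scores_excluded_per_statistic(self, scores):
        out = pg.summarize(scores, n_boot=50, seed=0)
        means = out[out.kind == "mean"].set_index(["statistic", "group"])["n"]
        for group in ("natural", "segment_freq"):
            assert means[("glob", group)] < means[("econ", group)]

    def test_role_swap_flips_auc(self, scores):
        fwd = pg.summarize(scores, comparisons=(("natural", "segment_freq"),), n_boot=10, seed=0)
        rev = pg.summarize(scores, comparisons=(("segment_freq", "natural"),), n_boot=10, seed=0)
        a = fwd[fwd.kind == "auc"].set_index("statistic").value
        b = rev[rev.kind == "auc"].set_index("statistic").value
        assert np.allclose(a + b, 1.0)


class TestCompareExternalSet:
    def test_identical_subsample_centres_at_half(self):
        rng = np.random.default_rng(2)
        sizes = np.repeat([5, 7, 9], 40)
        scores = rng.random(sizes.size)
        nat = ScoreSample("natural", scores, sizes)
        ext = ScoreSample("external", scores[:30], sizes[:30])
        res = pg.compare_external_set(ext, nat, n_draws=400, seed=0)
        assert res.ci_low < 0.5 < res.ci_high

    def test_shifted_external_interval_near_one(self):
        rng = np.random.default_rng(2)
        sizes = np.repeat([5, 7], 50)
        nat = ScoreSample("natural", rng.random(100), sizes)
        ext = ScoreSample("external", rng.random(20) - 10, np.repeat([5, 7], 10))
        res = pg.compare_external_set(ext, nat, n_draws=200, seed=0)
        assert res.ci_low == res.ci_high == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        sizes = np.repeat([4, 6], 30)
        nat = ScoreSample("natural", rng.random(60), sizes)
        ext = ScoreSample("external", rng.random(10), np.repeat([4, 6], 5))
        a = pg.compare_external_set(ext, nat, n_draws=100, seed=9)
        assert a == pg.compare_external_set(ext, nat, n_draws=100, seed=9)

    def test_unmatchable_sizes_rejected(self):
        nat = ScoreSample("natural", np.ones(3), np.array([4, 4, 4]))
        ext = ScoreSample("external", np.ones(2), np.array([5, 5]))
        with pytest.raises(ValueError, match="size-match"):
            pg.compare_external_set(ext, nat, n_draws=10, seed=0)
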