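import itertools

import numpy as np
import pytest

import phonogeom as pg
from phonogeom.enumeration import GeometrySample, RankTable


def brute_force_orbit(matrix):
    """All sorted-row forms reachable by column permutation + sign flips."""
    m = np.asarray(matrix, dtype=int)
    s, k = m.shape
    orbit = set()
    for perm in itertools.permutations(range(k)):
        for flips in itertools.product([-1, 1], repeat=k):
            t = m[:, perm] * np.array(flips)
            orbit.add(tuple(sorted(map(tuple, t.tolist()))))
    return orbit


class TestCanonicalForm:
    def test_column_reversal_same_key(self, iua):
        assert pg.canonical_form(iua) == pg.canonical_form(iua[:, ::-1])

    def test_polarity_flip_same_key(self, iua):
        m = iua.copy()
        m[:, 0] *= -1
        assert pg.canonical_form(iua) == pg.canonical_form(m)

    def test_two_point_configs_distinguished(self):
        near = np.array([[1, 1], [1, -1]], dtype=np.int8)
        far = np.array([[1, 1], [-1, -1]], dtype=np.int8)
        assert pg.canonical_form(near) != pg.canonical_form(far)

    def test_equal_keys_iff_same_orbit(self, rand_inventory):
        # brute-force orbit enumeration as the independent oracle
        rng = np.random.default_rng(23)
        mats = []
        for _ in range(12):
            k = int(rng.integers(2, 5))
            s = int(rng.integers(2, min(2**k, 6) + 1))
            mats.append(rand_inventory(rng, s, k))
        for a in mats:
            for b in mats:
                if a.shape != b.shape:
                    continue
                same_orbit = tuple(sorted(map(tuple, b.tolist()))) in brute_force_orbit(a)
                assert (pg.canonical_form(a) == pg.canonical_form(b)) == same_orbit

    def test_key_is_orbit_member(self, rand_inventory):
        rng = np.random.default_rng(31)
        m = rand_inventory(rng, 5, 3)
        assert pg.canonical_form(m) in brute_force_orbit(m)


class TestEnumerateGeometries:
    def test_saturated_cube_unique_geometry(self):
        sample = pg.enumerate_geometries(8, 3)
        assert len(sample.configs) == 1
        assert sample.provenance == "exhaustive"
        assert pg.count_minimal_pairs(sample.configs[0]) == 12
        assert pg.imbalance_sum(sample.configs[0]) == 0

    def test_two_segments_one_dimension(self):
        sample = pg.enumerate_geometries(2, 1)
        assert len(sample.configs) == 1

    def test_eight_on_four_nmp_range(self):
        sample = pg.enumerate_geometries(8, 4)
        vals = sorted({pg.count_minimal_pairs(m) for m in sample.configs})
        assert vals[0] == 4 and vals[-1] == 10

    def test_irreducibility_needs_enough_segments(self):
        assert pg.enumerate_geometries(3, 4).configs == []

    def test_impossible_size_rejected(self):
        with pytest.raises(ValueError):
            pg.enumerate_geometries(9, 3)

    def test_sampled_deterministic(self):
        a = pg.enumerate_geometries(8, 4, raw_budget=1, sample_budget=40, seed=9)
        b = pg.enumerate_geometries(8, 4, raw_budget=1, sample_budget=40, seed=9)
        assert a.provenance == b.provenance
        assert all(np.array_equal(x, y) for x, y in zip(a.configs, b.configs))
        assert a.provenance.startswith("sampled")


class TestRankTables:
    @pytest.fixture(scope="class")
    def table84(self):
        sample = pg.enumerate_geometries(8, 4)
        return pg.build_rank_tables(
            [sample.configs[0]], raw_budget=200_000, seed=0
        )

    def test_key_8_3_totally_determined(self, cube3):
        table = pg.build_rank_tables([cube3])
        assert table.mp_values[(8, 3)] == [12]
        assert table.im_values[(8, 3, 12)] == [0]
        assert pg.loc_score(12, (8, 3), table) is None  # omitted

    def test_key_8_4_im_values_at_max_nmp(self, table84):
        assert table84.im_values[(8, 4, 10)] == [8, 10, 12]
        assert table84.mp_values[(8, 4)][0] == 4
        assert table84.mp_values[(8, 4)][-1] == 10

    @pytest.mark.parametrize("nim,expected", [(8, 1.0), (10, 0.5), (12, 0.0)])
    def test_glob_descending_rank(self, table84, nim, expected):
        assert pg.glob_score(nim, (8, 4, 10), table84) == expected

    def test_loc_rank_extremes(self, table84):
        assert pg.loc_score(4, (8, 4), table84) == 0.0
        assert pg.loc_score(10, (8, 4), table84) == 1.0

    def test_loc_strictly_increasing_glob_strictly_decreasing(self, table84):
        locs = [pg.loc_score(v, (8, 4), table84) for v in table84.mp_values[(8, 4)]]
        assert locs == sorted(locs) and len(set(locs)) == len(locs)
        globs = [
            pg.glob_score(v, (8, 4, 10), table84)
            for v in table84.im_values[(8, 4, 10)]
        ]
        assert globs == sorted(globs, reverse=True)

    def test_attested_values_always_member(self, rand_inventory):
        rng = np.random.default_rng(2)
        mats = [rand_inventory(rng, 6, 4) for _ in range(5)]
        mats = [m for m in mats if len(np.unique(m, axis=0)) == 6]
        table = pg.build_rank_tables(mats, raw_budget=1, sample_budget=10, seed=0)
        for m in mats:
            s, k = m.shape
            assert pg.count_minimal_pairs(m) in table.mp_values[(s, k)]

    def test_missing_key_raises(self, table84):
        with pytest.raises(KeyError):
            pg.loc_score(1, (5, 2), table84)

    def test_json_roundtrip(self, table84, tmp_path):
        path = tmp_path / "tables.json"
        table84.to_json(path)
        back = RankTable.from_json(path)
        assert back.mp_values == table84.mp_values
        assert back.im_values == table84.im_values
        assert back.provenance == table84.provenance


class TestScoreInventory:
    def test_saturated_cube_econ_one_symmetries_omitted(self, cube3, encoded):
        inv = encoded(cube3, "cube")
        ss = pg.find_specs_exact(inv)
        table = pg.build_rank_tables([cube3])
        scores = pg.score_inventory(ss, inv, table)
        assert scores.econ == 1.0
        assert scores.loc is None and scores.glob is None
        assert scores.omit_reasons == {
            "loc": "single-attainable-value",
            "glob": "single-attainable-value",
        }

    def test_median_over_variants(self, iua, encoded):
        inv = encoded(iua, "iua")
        ss = pg.find_specs_exact(inv)
        table = pg.build_rank_tables(
            [iua[:, list(sp.feature_indices)] for sp in ss.specs]
        )
        scores = pg.score_inventory(ss, inv, table)
        assert scores.p == 2 and scores.n_variants == 3
        # econ for s=3, p=2: (3-3)/(4-3) = 0
        assert scores.econ == 0.0

    def test_single_key_variants_collapse_to_variant_score(self, encoded):
        m = np.array([[1, 1], [1, -1], [-1, 1]], dtype=np.int8)
        inv = encoded(m, "three")
        ss = pg.find_specs_exact(inv)
        assert {sp.feature_indices for sp in ss.specs} == {(0, 1)}
        table = pg.build_rank_tables([m])
        scores = pg.score_inventory(ss, inv, table)
        expected = pg.loc_score(pg.count_minimal_pairs(m), (3, 2), table)
        assert scores.loc == expected
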