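import itertools

import numpy as np
import pytest

import phonogeom as pg


@pytest.fixture
def iua():
    """The i/u/ɑ vowel triple on (back, round, low).

    i = (−,−,−), u = (+,+,−), ɑ = (+,−,+): backness and rounding are
    redundant for the i–u contrast, so three two-feature variant
    representations exist.
    """
    return np.array([[-1, -1, -1], [1, 1, -1], [1, -1, 1]], dtype=np.int8)


@pytest.fixture
def cube3():
    """The saturated 3-cube: all eight vertices."""
    return np.array(list(itertools.product([-1, 1], repeat=3)), dtype=np.int8)


@pytest.fixture
def rand_inventory():
    """Factory for random inventories with distinct rows."""

    def make(rng: np.random.Generator, s: int, k: int) -> np.ndarray:
        codes = rng.choice(2**k, size=s, replace=False)
        return np.array(
            [[1 if (c >> j) & 1 else -1 for j in range(k)] for c in codes],
            dtype=np.int8,
        )

    return make


def _encoded(matrix, lang="x", subsystem="whole"):
    return pg.EncodedInventory(lang, subsystem, matrix)


@pytest.fixture
def encoded():
    return _encoded


# --- session-scoped pipeline runs shared by the slower end-to-end tests ---

NULL_SYNTH_SEED = 11
PIPELINE_SEED = 5


def _study_run(beta_loc: float):
    cfg = pg.small_study_config(seed=NULL_SYNTH_SEED, beta_loc=beta_loc)
    run_cfg = pg.RunConfig(
        synthetic=cfg,
        subsystems=("whole",),
        control_kinds=("segment_freq",),
        cap=2000,
        sample_budget=300,
        n_boot=200,
        seed=PIPELINE_SEED,
    )
    return pg.run_pipeline(run_cfg)


@pytest.fixture(scope="session")
def null_run():
    """Full pipeline on 300 unbiased synthetic languages (whole subsystem)."""
    return _study_run(beta_loc=0.0)


@pytest.fixture(scope="session")
def biased_run():
    """Same study conditions with a minimal-pair generation bias of 2."""
    return _study_run(beta_loc=2.0)
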