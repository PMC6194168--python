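import numpy as np
import pandas as pd
import pytest

import funcmeas as fm


@pytest.fixture(scope="session")
def design():
    """The 5 audio x 3 tactile (+ both unimodal margins) x 6 reps design."""
    return fm.paper_design()


@pytest.fixture(scope="session")
def small_design():
    """2 x 2 with margins, 1 rep — 8 cells, small enough for grid oracles."""
    return fm.build_design(["A1", "A2"], ["T1", "T2"], reps=1)


@pytest.fixture(scope="session")
def noiseless_cohort(design):
    """Equal-weight averaging cohort with zero trial noise (exact algebra)."""
    cfg = fm.make_paper_like_config(seed=101, noise_sd=0.0)
    return fm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_cohort, design):
    return fm.cell_means(noiseless_cohort.records, design)


@pytest.fixture(scope="session")
def noisy_cohort(design):
    """Study-like cohort at the default trial noise (10 rating units)."""
    return fm.simulate_cohort(fm.make_paper_like_config(seed=202))


@pytest.fixture(scope="session")
def noisy_table(noisy_cohort, design):
    return fm.cell_means(noisy_cohort.records, design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_level_means(values: dict[str, list[float]]) -> pd.DataFrame:
    """Subjects x levels frame from {level: per-subject values}."""
    return pd.DataFrame(values)
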