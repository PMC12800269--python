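import numpy as np
import pytest

import phenolink as pl


@pytest.fixture(scope="session")
def flat_climate():
    """Constant daily temperature of 1.0 over 30 years."""
    dates = np.arange(
        np.datetime64("1980-01-01"), np.datetime64("2010-01-01"), dtype="datetime64[D]"
    )
    return pl.DailyClimate("temperature", dates, np.ones(len(dates)))


@pytest.fixture(scope="session")
def seeded_climate():
    return pl.simulate_daily_climate(1990, 32, seed=101)


@pytest.fixture(scope="session")
def strong_signal_truth():
    return pl.TruthParams(
        cz_true=-0.8, zg_true=0.3, cg_true=-0.2, pg_true=-0.4,
        true_window=(6, 3), trait_resid_sd=0.1,
    )


@pytest.fixture(scope="session")
def seeded_study(strong_signal_truth, seeded_climate):
    return pl.simulate_study(strong_signal_truth, seeded_climate, 30, seed=11)


@pytest.fixture(scope="session")
def small_tree():
    return pl.parse_newick("((A:1,B:1):1,C:2);")
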