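import numpy as np
import pandas as pd
import pytest

from rdsem import (GeneratingConfig, PanelDataset, default_generating_config,
                   expand_time_lattice, fit_mcmc, generate_panel,
                   impose_missingness)


def toy_frame():
    """Three persons, two occasions, one missing SWLS cell."""
    return pd.DataFrame({
        "person_id": ["a", "a", "b", "b", "c", "c"],
        "month": [0, 3, 0, 3, 0, 3],
        "dudit_c": [4.0, 2.0, 0.0, 8.0, 1.0, 3.0],
        "swls": [20.0, np.nan, 15.0, 18.0, 35.0, 5.0],
        "scl90r_gsi": [1.2, 1.0, 0.4, 0.8, 2.5, 2.0],
        "drug_free_friends": [1, 1, 0, 0, 1, 1],
        "age": [25.0, 25.0, 30.0, 30.0, 47.0, 47.0],
        "gender": [1, 1, 0, 0, 1, 1],
    })


@pytest.fixture
def toy_panel():
    df = toy_frame()
    persons = df[["person_id", "age", "gender"]].drop_duplicates()
    return PanelDataset(records=df, persons=persons, schedule=(0, 3))


@pytest.fixture(scope="session")
def default_config():
    return default_generating_config(n_persons=164, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-person cohort with missingness, lattice-expanded, ready to fit."""
    cfg = default_generating_config(n_persons=50, seed=7)
    panel = impose_missingness(generate_panel(cfg, seed=7), cfg, seed=8)
    return cfg, expand_time_lattice(panel)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A short two-chain fit shared across reporting/diagnostic tests."""
    _, panel = small_cohort
    return fit_mcmc(panel, chains=2, iterations=700, seed=5)
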