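import numpy as np
import pandas as pd
import pytest

from pdsmeq.contrasts import build_design
from pdsmeq.synthetic import GeneratorConfig, default_true_params, simulate_dataset


def make_dataset(scenario="null", n=2000, seed=0, continuous=True, **kwargs):
    """Simulated cohort plus its contrast design."""
    cfg = GeneratorConfig(
        n=n, true_params=default_true_params(scenario), seed=seed,
        continuous=continuous, **kwargs,
    )
    table = simulate_dataset(cfg)
    return table, build_design(table)


@pytest.fixture(scope="session")
def null_cohort():
    """Medium null-scenario continuous cohort shared across tests."""
    return make_dataset("null", n=3000, seed=17)


@pytest.fixture(scope="session")
def dif_cohort():
    """final_model continuous cohort at a moderate n."""
    return make_dataset("final_model", n=4000, seed=23)


@pytest.fixture
def toy_table():
    """Six persons, one per intersectional cell, fixed small responses."""
    rows = []
    pid = 1
    for race in ("Black", "Latinx", "White"):
        for sex in ("female", "male"):
            rows.append(
                {"person_id": pid, **{f"item_{j}": ((pid + j) % 5) + 1 for j in range(1, 8)},
                 "sex": sex, "race_ethnicity": race, "weight": 1.0}
            )
            pid += 1
    return pd.DataFrame(rows)
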