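import numpy as np
import pandas as pd
import pytest

import t1dapc as t
from t1dapc.pipeline import model_table


@pytest.fixture(scope="session")
def binary_effect():
    return [t.TrueEffect(site="carcinoma", sex="*", binary_multiplier=1.5)]


@pytest.fixture(scope="session")
def small_cohort(binary_effect):
    """A small two-register cohort with true binary HR 1.5."""
    cfg = t.desk_binary_config(seed=42, persons=6000)
    persons = t.simulate_t1d_cohort(cfg, binary_effect)
    return cfg, persons


@pytest.fixture(scope="session")
def small_fit_inputs(small_cohort):
    """Cells + population table ready for model fitting."""
    cfg, persons = small_cohort
    seg = t.split_cohort(persons, bands=cfg.bands, variant="all_sites")
    cells = t.tabulate(seg, by=("country", "sex", "age", "period", "duration"))
    pop = t.simulate_registry_tables(cfg)
    tab = model_table(pop, cells, sex="M")
    return cfg, cells, pop, tab


def random_persons(rng, n, with_cancer=True):
    """Random valid PersonRecords frames for property tests."""
    birth = rng.uniform(1940, 1995, n)
    dx = birth + rng.uniform(0, 39.9, n)
    start = 1995.0
    entry = np.maximum(start, dx)
    exit_ = entry + rng.uniform(0.01, 12.0, n)
    cancer = np.where(rng.uniform(size=n) < (0.4 if with_cancer else 0.0),
                      entry + rng.uniform(0, 1, n) * (exit_ - entry), np.nan)
    return pd.DataFrame({
        "id": np.arange(n), "country": "X", "sex": "M",
        "birth": birth, "dx": dx, "cancer": cancer,
        "site": np.where(np.isfinite(cancer), "c1", None),
        "death": np.nan, "entry": entry, "exit": exit_,
    })
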