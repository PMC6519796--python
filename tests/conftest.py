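import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from prognopipe.study import StudyConfig, make_cohort, run_comparator_battery
from prognopipe.synth import SyntheticConfig, generate_cohort, inject_missingness

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort: n=20,000, 1.13% prevalence, missingness."""
    cfg = SyntheticConfig(seed=1)
    table, truth = generate_cohort(cfg)
    injected = inject_missingness(table, cfg)
    return injected, truth, cfg


@pytest.fixture(scope="session")
def complete_cohort():
    """Same default cohort before missingness injection."""
    cfg = SyntheticConfig(seed=1)
    table, truth = generate_cohort(cfg)
    return table, truth, cfg


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 4,000-participant cohort with a common outcome for model tests."""
    cfg = SyntheticConfig(n_participants=4000, event_prevalence=0.1, seed=5)
    table, truth = generate_cohort(cfg)
    injected = inject_missingness(table, cfg)
    return injected, truth, cfg


@pytest.fixture(scope="session")
def battery_result():
    """Comparator battery on the default nonlinear fixture (reduced budget)."""
    cfg = StudyConfig(synthetic=SyntheticConfig(n_participants=20_000, seed=1),
                      outer_k=3, inner_k=3, budget=12, top_k=3, seed=1)
    table, meta, truth = make_cohort(cfg)
    battery = run_comparator_battery(table, meta, cfg)
    return battery, table, meta, truth, cfg


@pytest.fixture()
def toy_classification():
    """Well-separated two-class data with mild missingness."""
    rng = np.random.default_rng(0)
    n = 600
    X = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"v{i}" for i in range(6)])
    y = (rng.random(n) < expit(2.0 * X["v0"] - 1.2 * X["v1"])).astype(int)
    X.iloc[rng.random((n, 6)) < 0.08] = np.nan
    return X, y
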