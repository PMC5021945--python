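import numpy as np
import pandas as pd
import pytest

from ffpesig import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete matched cohort used across test modules."""
    cfg = SimulationConfig(n_samples=30, n_genes=40, n_prognostic=5, seed=1)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_survival(n, seed=0, beta=0.0, x=None, censor_frac=0.3, round_times=False):
    """Simple exponential survival dataset for unit tests.

    Returns (x, time, event) with continuous (untied) times unless
    ``round_times`` introduces ties.
    """
    gen = np.random.default_rng(seed)
    if x is None:
        x = gen.normal(0.0, 1.0, n)
    t_event = gen.exponential(50.0 * np.exp(-beta * x))
    censored = gen.uniform(0.0, 1.0, n) < censor_frac
    time = np.where(censored, t_event * gen.uniform(0.2, 0.9, n), t_event)
    event = (~censored).astype(int)
    if round_times:
        time = np.round(time, 0) + 1.0
    else:
        time = time + 1e-9
    return x, time, event


def clinical_frame(time, event, samples=None, batch="B1"):
    """Wrap one endpoint's (time, event) into the clinical-table layout."""
    n = len(time)
    idx = samples if samples is not None else [f"S{i:03d}" for i in range(n)]
    return pd.DataFrame({
        "os_time_months": time,
        "os_event": event,
        "dfs_time_months": time,
        "dfs_event": event,
        "batch": batch,
    }, index=pd.Index(idx, name="sample_id"))
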