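import numpy as np
import pandas as pd
import pytest

from olivescan.pipeline import RunConfig, simulate_samples


@pytest.fixture(scope="session")
def benchmark_table() -> pd.DataFrame:
    """Default-noise synthetic benchmark (3 cultivars, 51 samples each)."""
    cfg = RunConfig(master_seed=1, n_times=17, reps_per_time=3)
    return simulate_samples(cfg)


@pytest.fixture(scope="session")
def noiseless_table() -> pd.DataFrame:
    """Zero-noise benchmark: traits are deterministic functions of time."""
    cfg = RunConfig(
        master_seed=1,
        n_times=17,
        reps_per_time=3,
        noise_sd_channel=(0.0, 0.0, 0.0),
        noise_sd_trait=(0.0, 0.0),
    )
    return simulate_samples(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def standardize(X: np.ndarray) -> np.ndarray:
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
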