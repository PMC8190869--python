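import warnings

import numpy as np
import pandas as pd
import pytest

from methdmr.simulate import SimulationConfig, simulate_cohort
from methdmr.tiling import WindowMatrix, tile_windows

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11, n_windows=150, cpgs_per_window=6.0,
        n_planted_prognostic=8, n_planted_dmr=8, n_planted_trend=8,
        n_planted_predictive=6,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_wm(small_cohort):
    _, covs, _ = small_cohort
    return tile_windows(covs)


def make_window_matrix(meth, cov, chrom="chr1", window_size=1000,
                       samples=None):
    """Small WindowMatrix straight from count arrays (windows x samples)."""
    meth = np.asarray(meth, dtype=np.int64)
    cov = np.asarray(cov, dtype=np.int64)
    w = meth.shape[0]
    if samples is None:
        samples = [f"s{i}" for i in range(meth.shape[1])]
    wins = pd.DataFrame({
        "chrom": [chrom] * w,
        "start": np.arange(w) * window_size + 1,
        "end": (np.arange(w) + 1) * window_size,
    })
    return WindowMatrix(wins, list(samples), meth, cov,
                        (cov > 0).astype(np.int64), window_size)


@pytest.fixture
def window_matrix_factory():
    return make_window_matrix
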