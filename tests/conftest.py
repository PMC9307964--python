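from __future__ import annotations

import numpy as np
import pytest

from exopair.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples_per_cohort=150,
        n_normal=25,
        n_mrna_seed=20,
        n_lncrna=150,
        n_coexpressed=20,
        n_de=14,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def random_monotone_distortion(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random strictly increasing per-sample transform of non-negative data."""
    n = values.shape[1]
    a = rng.uniform(0.2, 3.0, size=n)
    b = rng.uniform(0.5, 2.0, size=n)
    c = rng.uniform(0.0, 10.0, size=n)
    return a[None, :] * np.power(values, b[None, :]) + c[None, :]
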