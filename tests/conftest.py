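import numpy as np
import pandas as pd
import pytest

from heckcrash.synthetic_data import (CovariateSpec, SimulationConfig,
                                      simulate_dataset)


def compact_config(n, rho, sigma=0.5, seed=0):
    """A two-covariate selection system with a strong exclusion restriction
    (z1 enters selection only), used for fast Monte-Carlo checks."""
    return SimulationConfig(
        n=n,
        covariate_specs=[CovariateSpec("x1", "normal", {"mean": 0, "sd": 1}),
                         CovariateSpec("z1", "normal", {"mean": 0, "sd": 1})],
        x_cols=["x1"],
        z_cols=["x1", "z1"],
        gamma_true=np.array([0.5, 0.8, 1.0]),
        beta_true=np.array([1.0, 0.7]),
        rho_true=rho,
        sigma_true=sigma,
        seed=seed,
    )


@pytest.fixture
def compact_dataset():
    """n=5,000 draw from the compact system at rho=0.6, sigma=0.5."""
    return simulate_dataset(compact_config(5000, rho=0.6, sigma=0.5, seed=42))


@pytest.fixture
def intersection_frame():
    """A small intersection-year table with hand-set crash counts."""
    rng = np.random.default_rng(7)
    n = 12
    return pd.DataFrame({
        "intersection_id": [f"I{i:03d}" for i in range(n)],
        "year": [2002 + (i % 2) for i in range(n)],
        "aadt": rng.uniform(5_000, 60_000, n).round(0),
        "slight_count": [0, 1, 3, 0, 2, 0, 1, 0, 4, 1, 0, 2],
        "ksi_count":    [0, 0, 1, 1, 0, 0, 0, 0, 1, 1, 0, 0],
        "reciprad": rng.uniform(0.02, 0.15, n),
        "cycletime": rng.uniform(60, 130, n),
        "tramstop": rng.binomial(1, 0.2, n),
        "kln": rng.binomial(1, 0.5, n),
        "speed": np.full(n, 50.0),
        "comveh": rng.uniform(0.05, 0.4, n),
        "lanewidth": rng.uniform(2.8, 4.0, n),
    })
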