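import numpy as np
import pandas as pd
import pytest

from selfthin.synthetic_data import SimulationConfig, simulate_network


@pytest.fixture(scope="session")
def network():
    """Default synthetic plot network (the package's standard study conditions)."""
    return simulate_network(SimulationConfig())


@pytest.fixture(scope="session")
def static_plots(network):
    return network.plots[~network.plots["is_dynamic"]].reset_index(drop=True)


def ald_noise(rng: np.random.Generator, sigma: float, tau: float, size: int) -> np.ndarray:
    """Asymmetric-Laplace(0, sigma, tau) draws: mixture of two exponentials."""
    pos = rng.random(size) < (1.0 - tau)
    return np.where(pos,
                    rng.exponential(sigma / tau, size),
                    -rng.exponential(sigma / (1.0 - tau), size))


def frontier_plots(rng: np.random.Generator, n_plots: int, obs_per_plot: int,
                   beta=(12.0, -1.6), re_sd=0.1, noise="ald", tau=0.95,
                   sigma=0.1, sigma_v=0.08, sigma_u=0.25) -> pd.DataFrame:
    """Grouped (ln dg, ln N) data around a Reineke line, for fitter checks."""
    rows = []
    for i in range(n_plots):
        u = rng.normal(0, re_sd) if re_sd > 0 else 0.0
        for _ in range(obs_per_plot):
            x = rng.uniform(2.5, 3.9)
            if noise == "ald":
                e = ald_noise(rng, sigma, tau, 1)[0]
            elif noise == "gauss":
                e = rng.normal(0, sigma)
            elif noise == "frontier":  # composed error of stochastic frontier
                e = rng.normal(0, sigma_v) - abs(rng.normal(0, sigma_u))
            else:
                raise ValueError(noise)
            y = beta[0] + u + beta[1] * x + e
            rows.append(dict(plot_id=f"p{i:04d}", n_ha=np.exp(y), dg_cm=np.exp(x)))
    return pd.DataFrame(rows)
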