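import numpy as np
import pytest

from porcycle.pipelines import simulate_merged
from porcycle.schemes import KineticScheme


def random_scheme(rng: np.random.Generator, max_compartments: int = 5) -> KineticScheme:
    """Random first-order compartmental scheme with rates log-uniform in
    [1e3, 1e12] s^-1, random topology (cycles allowed) and random losses."""
    n = int(rng.integers(2, max_compartments + 1))
    k = np.zeros((n, n))
    for j in range(n):
        for i in range(n):
            if i != j and rng.random() < 0.4:
                k[i, j] = 10 ** rng.uniform(3, 12)
    loss = 10 ** rng.uniform(3, 12, n) * (rng.random(n) < 0.5)
    for j in range(n):
        k[j, j] = -(k[:, j].sum() - k[j, j]) - loss[j]
    p0 = rng.dirichlet(np.ones(n))
    return KineticScheme(tuple(f"c{i}" for i in range(n)), k, p0)


def scheme_time_grid(scheme: KineticScheme, n: int = 30) -> np.ndarray:
    rates = -np.diag(scheme.rate_matrix)
    rates = rates[rates > 0]
    tmax = 5.0 / max(rates.min(initial=1e3), 1e3)
    return np.geomspace(tmax * 1e-9, tmax, n)


@pytest.fixture(scope="session")
def wt_merged_noiseless():
    # ideal merging: both windows are generated on a common scale
    return simulate_merged("wildtype_branched", seed=0, noise_relative=0.0, scale=1.0)


@pytest.fixture(scope="session")
def variant_merged_noiseless():
    return simulate_merged("variant_sequential", seed=0, noise_relative=0.0, scale=1.0)
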