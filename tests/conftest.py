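import numpy as np
import pytest

from netdiff import DesignPair


def make_design(
    rng: np.random.Generator,
    n: int = 25,
    p: int = 8,
    n_signal: int = 3,
    sigma: float = 0.1,
) -> tuple[DesignPair, np.ndarray, np.ndarray]:
    """Random centered design pair with a planted sparse signal.

    The second condition's coefficients rewire one signal entry so the
    pair carries a genuine network change.
    """
    za = rng.standard_normal((n, p))
    zb = rng.standard_normal((n, p))
    beta = np.zeros(p)
    idx = rng.choice(p, size=n_signal, replace=False)
    beta[idx] = rng.uniform(0.5, 1.5, n_signal) * rng.choice([-1, 1], n_signal)
    beta_tilde = beta.copy()
    beta_tilde[idx[0]] = 0.0
    ya = za @ beta + sigma * rng.standard_normal(n)
    yb = zb @ beta_tilde + sigma * rng.standard_normal(n)
    return DesignPair.from_raw(ya, za, yb, zb), beta, beta_tilde


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def network_benchmark():
    """Changed-edge benchmark on simulated network pairs, shared by the
    ranking-quality tests.

    Thirty replicates of the 50-gene / 62-edge / 6-changes generator at
    n = 100 samples and measurement-noise variance 0.05 (thirty so the
    paired sign test across replicates has reasonable power).  Stability
    selection runs on per-gene penalty grids subsampling the default
    grid range (decay factors 0.7^3 / 0.8^3, 4 x 4 pairs) with 4
    half-sample runs and a capped solver budget, for both the joint
    method and the per-condition lasso baseline.
    """
    import logging

    from netdiff.benchmarks import run_network_benchmark
    from netdiff.simulate import NetSimConfig

    logging.getLogger("netdiff.network").setLevel(logging.ERROR)
    return run_network_benchmark(
        n_replicates=30,
        seed=1,
        sim_config=NetSimConfig(p=50, n_edges=62, n_changed=6, n=100, sigma2_meas=0.05),
    )
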