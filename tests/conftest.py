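import numpy as np
import pytest

from ogacp import RunConfig, detect, gen_linear_cp, gen_periodic_ar, periodic_ar_spec


@pytest.fixture(scope="session")
def reference_draw():
    """One seeded draw from the reference periodic-AR design."""
    return gen_periodic_ar(np.random.default_rng(20250901))


@pytest.fixture(scope="session")
def reference_fit(reference_draw):
    series, _ = reference_draw
    return detect(series, RunConfig())


@pytest.fixture(scope="session")
def noiseless_reference():
    """Deterministic (error-free) draw from the reference design."""
    return gen_linear_cp(periodic_ar_spec(noise_sd=0.0))


def random_instance(rng, n=40, p=8, snr=2.0):
    """Small random regression instance with a sparse truth, for oracles."""
    Z = rng.normal(size=(n, p))
    k = max(2, p // 3)
    support = rng.choice(p, size=k, replace=False)
    beta = np.zeros(p)
    beta[support] = rng.normal(scale=snr, size=k)
    y = Z @ beta + rng.normal(size=n)
    return y - y.mean(), Z - Z.mean(axis=0)
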