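import pytest

from mvnmix import ScenarioSpec, simulate_counts


@pytest.fixture
def toy_counts():
    """Small matrix with known moments: m1=2.5, m2=7.5, m11=7."""
    return [[1, 2], [3, 4]]


@pytest.fixture
def anticorrelated_counts():
    """D1 = -1: perfectly anti-correlated visits."""
    return [[2, 0], [0, 2]]


@pytest.fixture
def poisson_counts_t2():
    """One simulated Poisson dataset, lam=5, p=0.3, S=100, T=2."""
    spec = ScenarioSpec(family="poisson", lam=5, p=0.3, T=2, S=100, n_sim=1, seed=1234)
    return simulate_counts(spec)


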