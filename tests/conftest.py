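import pytest

import plannsim as ps


@pytest.fixture(scope="session")
def yearly():
    return ps.make_scheme("yearly")


@pytest.fixture(scope="session")
def spec61():
    return ps.censoring_specs()["61-scenario1"]


@pytest.fixture(scope="session")
def dataset(spec61):
    """One medium synthetic dataset under the default generator (61% cens)."""
    return ps.simulate_dataset(400, spec61, master_seed=11)


@pytest.fixture(scope="session")
def train_test(dataset):
    return ps.split_train_test(dataset, ps.replicate_rng(11, 0, 3))


@pytest.fixture(scope="session")
def train_long(train_test, yearly):
    return ps.to_long_train(train_test[0], yearly)


def random_survival_fixture(rng, n):
    """Random right-censored data with a random prognostic index."""
    times = rng.exponential(3.0, n).round(3) + 0.001
    events = (rng.random(n) < 0.6).astype(int)
    pi = rng.normal(size=n).round(2)  # rounding creates some PI ties
    return pi, times, events
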