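import numpy as np
import pytest

from bcisa.chains import ChainSpec, ObservationSeries


def random_chain(rng, n_states, length):
    """Random stochastic chain with a discrete emission table."""
    prior = rng.dirichlet(np.ones(n_states))
    transition = rng.dirichlet(np.ones(n_states), size=n_states)
    table = rng.uniform(0.05, 1.0, size=(n_states, n_states))

    spec = ChainSpec(
        n_states=n_states,
        length=length,
        prior=prior,
        transition=transition,
        emission=lambda s, v: float(table[s, int(v)]),
    )
    obs = ObservationSeries(values=rng.integers(0, n_states, size=length))
    return spec, obs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
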