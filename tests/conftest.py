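import numpy as np
import pytest

from bsds.model import ARParams, FAParams, HMMParams, StateParameters


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_state_parameters(K, D, P, rng, ar_max=0.8):
    """Random valid parameters for oracle tests (well-conditioned)."""
    fa, ar = [], []
    for _ in range(K):
        fa.append(
            FAParams(
                U=rng.normal(size=(D, P)),
                mu=rng.normal(size=D),
                psi=rng.uniform(0.2, 1.0, size=D),
            )
        )
        ar.append(
            ARParams(
                V=rng.uniform(-ar_max, ar_max, size=(1, P)),
                m=rng.normal(scale=0.3, size=P),
                sigma=rng.uniform(0.3, 1.0, size=P),
            )
        )
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    return StateParameters(hmm=HMMParams(pi=pi, A=A), fa=tuple(fa), ar=tuple(ar))


@pytest.fixture()
def make_params(rng):
    return lambda K, D, P, **kw: random_state_parameters(K, D, P, rng, **kw)
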