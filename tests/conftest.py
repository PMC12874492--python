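import numpy as np
import pytest

from mfsunet.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One 64x64 phantom at default difficulty (session-cached)."""
    return generate_phantom(PhantomConfig(image_size=64), seed=7)


def random_ssm_instance(rng, L=32, D=4, N=8):
    """A random stable selective-SSM instance (A <= 0, small steps)."""
    from mfsunet.ssm import SSMParams, SSMSequence
    params = SSMParams(
        A=-rng.uniform(0.05, 3.0, size=(D, N)),
        B_t=rng.normal(size=(L, N)),
        C_t=rng.normal(size=(L, N)),
        delta_t=rng.uniform(0.01, 1.0, size=(L, D)),
    )
    seq = SSMSequence(rng.normal(size=(L, D)))
    return seq, params
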