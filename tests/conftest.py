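import numpy as np
import pytest

from temkit.model import TEM, StreamSpec


@pytest.fixture(scope="session")
def small_spec():
    """Two-stream spec small enough for fast forward/backward tests."""
    return StreamSpec(n_g=(6, 5), n_f=(2, 2), ns=10, ns_c=5)


@pytest.fixture()
def small_model(small_spec):
    m = TEM(small_spec, n_actions=3, seed=1)
    rng = np.random.default_rng(2)
    for s in range(small_spec.n_streams):
        w = m.params[f"Wa{s}"]
        w.data = w.data + rng.normal(0, 0.1, w.data.shape)
    return m


@pytest.fixture(scope="session")
def default_spec():
    """The full-size five-stream configuration."""
    return StreamSpec()
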