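import numpy as np
import pytest

import spikesim as ss


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_two_layer(n_pre=3, n_post=2, w=None, rule=None, seed=0, dt=1.0,
                   **conn_kwargs):
    """Input -> LIF network used across network/learning tests."""
    net = ss.Network(dt=dt, seed=seed)
    net.add_layer("pre", ss.InputNodes(n_pre))
    post = ss.LIFNodes(n_post)
    net.add_layer("post", post)
    if w is None:
        w = np.ones((n_pre, n_post))
    net.add_connection(
        "pre", "post",
        ss.Connection(net.layers["pre"], post, w=w, update_rule=rule,
                      **conn_kwargs),
    )
    return net


@pytest.fixture
def two_layer_net():
    return make_two_layer()
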