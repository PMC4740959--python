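import numpy as np
import pytest

from hybridesn.topology import TopologySpec, build_topology


@pytest.fixture
def hybrid25():
    return build_topology(TopologySpec(kind="hybrid", n=25, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_weights(kind="hybrid", n=10, k=1, seed=0, **kw):
    return build_topology(TopologySpec(kind=kind, n=n, k=k, seed=seed, **kw))
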