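import numpy as np
import pytest

from ctrnn_selfopt import (
    ConditionSpec,
    NodeParams,
    WeightMatrix,
    compute_bias,
    generate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sm_alpha():
    """A seeded symmetric-modular original matrix at the default settings."""
    return generate(ConditionSpec("SM", seed=7))


@pytest.fixture
def sm_params(sm_alpha, rng):
    return NodeParams.random(30, rng, weights=sm_alpha)


def make_toy_params(
    W: WeightMatrix,
    tau=1.0,
    gain=1.0,
    dt=0.1,
    duration=50.0,
    bias_from_weights=True,
) -> NodeParams:
    """NodeParams for a small hand-built network (scalar tau/gain allowed)."""
    n = W.n_nodes
    bias = compute_bias(W) if bias_from_weights else np.zeros(n)
    return NodeParams(
        tau=np.full(n, float(tau)),
        gain=np.full(n, float(gain)),
        bias=bias,
        dt=dt,
        duration=duration,
    )
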