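import numpy as np
import pytest

from reconsim import (
    build_default_patterns,
    make_protocol,
    standard_sessions,
    weights_after,
)


@pytest.fixture(scope="session")
def patterns():
    return build_default_patterns()


@pytest.fixture(scope="session")
def trained_weights(patterns):
    """Weights of one replicate after the standard training protocol
    (train unrelated memory, decay, train shock memory)."""
    return weights_after(standard_sessions(None, pretest=False), seed=11, patterns=patterns)


@pytest.fixture(scope="session")
def extinguished_weights(patterns):
    """Weights after training plus a single long (t=10) extinction session."""
    return weights_after(standard_sessions(10.0, pretest=False)[:-1], seed=11, patterns=patterns)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quick_protocol():
    """Small standard protocol spec factory for fast integration tests."""

    def _make(t=None, n_replicates=20, seed=7, **arm):
        return make_protocol(
            standard_sessions(t, pretest=False, **arm),
            n_replicates=n_replicates,
            seed=seed,
        )

    return _make
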