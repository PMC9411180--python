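import numpy as np
import pytest

from skullnet import AnatomicalNetwork
from skullnet.synthetic import _path_network, _two_cliques, make_fixture_suite


@pytest.fixture
def path_net() -> AnatomicalNetwork:
    """The 3-bone path A-B-C, the smallest nontrivial network."""
    return _path_network()


@pytest.fixture
def two_cliques() -> AnatomicalNetwork:
    """Two 4-cliques joined by a single bridge edge."""
    return _two_cliques()


@pytest.fixture
def triangle() -> AnatomicalNetwork:
    return AnatomicalNetwork("K3", ("A", "B", "C"), 1 - np.eye(3, dtype=int))


def complete_net(n: int) -> AnatomicalNetwork:
    return AnatomicalNetwork(
        f"K{n}", tuple(f"v{i}" for i in range(n)), 1 - np.eye(n, dtype=int)
    )


def er_net(n: int, p: float, seed: int) -> AnatomicalNetwork:
    rng = np.random.default_rng(seed)
    upper = np.triu((rng.random((n, n)) < p).astype(int), 1)
    return AnatomicalNetwork(
        f"er{seed}", tuple(f"v{i}" for i in range(n)), upper + upper.T
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(out, seed=0)
    return out
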