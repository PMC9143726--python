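import numpy as np
import pytest

import hosgns as hg


@pytest.fixture(scope="session")
def toy_graph():
    return hg.toy_fig1_graph()


@pytest.fixture(scope="session")
def synth_graph():
    """Default-scale community graph shared by read-only tests."""
    h, labels = hg.generate_community_tvg(hg.SynthConfig(seed=42))
    return h, labels


@pytest.fixture(scope="session")
def small_graph():
    """A smaller, denser graph for tests that train embeddings."""
    cfg = hg.SynthConfig(n_nodes=30, n_communities=3, n_times=15,
                         activity=0.8, p_in=0.45, p_out=0.05, seed=7)
    h, labels = hg.generate_community_tvg(cfg)
    return h, labels


def random_tvg(n_nodes=10, n_times=5, p=0.3, seed=0):
    """Erdos-Renyi-per-snapshot temporal graph for brute-force oracles."""
    rng = np.random.default_rng(seed)
    events = []
    for k in range(n_times):
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < p:
                    events.append(hg.TemporalEvent(i, j, k, float(rng.integers(1, 5))))
    assert all(any(e.k == k for e in events) for k in range(n_times))
    return hg.TimeVaryingGraph(n_nodes=n_nodes, n_times=n_times, events=events)
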