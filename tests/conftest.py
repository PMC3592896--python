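import numpy as np
import pytest

from ipfddi import build_network, fig1_fixture


def random_network(rng, n_drugs, edge_prob=0.15, with_effects=True):
    """Erdős–Rényi-style random symmetric network over drugs g000..g{n-1}."""
    ids = [f"g{i:03d}" for i in range(n_drugs)]
    edges = []
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            if rng.random() < edge_prob:
                effect = f"effect {ids[i]}+{ids[j]}" if with_effects else ""
                edges.append((ids[i], ids[j], effect))
    if not edges:  # guarantee at least one edge so build_network succeeds
        edges.append((ids[0], ids[1], "effect fallback"))
    return build_network(edges, extra_drugs=ids)


@pytest.fixture
def fig1():
    return fig1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20130308)
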