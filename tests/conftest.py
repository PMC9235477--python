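"""Shared fixtures: toy graphs, walk oracles, and the (expensive)
session-scoped training runs reused across unit and acceptance tests."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from hybridppi import (
    BenchmarkConfig,
    PPINetwork,
    build_network,
    synth_benchmark,
)
from hybridppi.pipeline import (
    COSUP_BENCHMARK,
    SMOKE_BENCHMARK,
    cosupervision_comparison,
    embed_benchmark,
    random_baseline_aupr,
    train_on_benchmark,
)


# ---------------------------------------------------------------------------
# graphs

@pytest.fixture
def path3() -> PPINetwork:
    return build_network([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def triangle_pendant() -> PPINetwork:
    """Unit-weight triangle A-B-C plus pendant D attached to A."""
    return build_network([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0),
                          ("A", "D", 1.0)])


@pytest.fixture
def cycle4() -> PPINetwork:
    return build_network([("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0),
                          ("D", "A", 1.0)])


def small_connected_graphs():
    """A fixture suite of connected graphs with <= 8 nodes, mixing
    topologies and weights (periodic/bipartite cases included)."""
    graphs = []

    def from_nx(g, tag, weights=None):
        net = PPINetwork()
        for i, (a, b) in enumerate(g.edges()):
            w = 1.0 if weights is None else weights[i % len(weights)]
            net.add_edge(f"n{a}", f"n{b}", w)
        return tag, net

    graphs.append(from_nx(nx.path_graph(3), "path3"))
    graphs.append(from_nx(nx.path_graph(5), "path5"))
    graphs.append(from_nx(nx.cycle_graph(4), "cycle4"))
    graphs.append(from_nx(nx.cycle_graph(5), "cycle5"))
    graphs.append(from_nx(nx.star_graph(4), "star5"))
    graphs.append(from_nx(nx.complete_graph(4), "K4"))
    graphs.append(from_nx(nx.path_graph(4), "weighted-path4", weights=[1.0, 2.5, 0.5]))
    graphs.append(from_nx(nx.wheel_graph(6), "wheel6"))
    graphs.append(from_nx(nx.complete_bipartite_graph(2, 3), "K23"))
    rng = np.random.default_rng(42)
    for k in range(4):
        g = nx.gnp_random_graph(8, 0.45, seed=int(rng.integers(0, 1 << 16)))
        if nx.is_connected(g):
            graphs.append(from_nx(g, f"gnp8-{k}",
                                  weights=list(rng.uniform(0.2, 3.0, size=6))))
    return graphs


def walk_oracle_states(net: PPINetwork, k: int = 4000):
    """Truncated k-step random-walk visit-count oracle.

    Accumulates sum_t e_i P^t and returns the Cesaro average of the last
    two partial sums, which also converges for periodic (bipartite)
    chains; row differences of the limit are the diffusion states'.
    """
    nodes = tuple(sorted(net.nodes))
    W = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
    P = W / W.sum(axis=1, keepdims=True)
    acc = np.eye(len(nodes))
    cur = np.eye(len(nodes))
    prev = acc.copy()
    for _ in range(k):
        cur = cur @ P
        prev = acc.copy()
        acc = acc + cur
    return nodes, (acc + prev) / 2.0


def random_small_network(rng: np.random.Generator, n_max: int = 10) -> PPINetwork:
    """A random connected weighted network with 3..n_max nodes."""
    n = int(rng.integers(3, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 1 << 16)))
        if nx.is_connected(g):
            break
    net = PPINetwork()
    for a, b in g.edges():
        net.add_edge(f"n{a}", f"n{b}", float(rng.uniform(0.2, 3.0)))
    return net


def all_node_pairs(net: PPINetwork):
    return itertools.combinations(sorted(net.nodes), 2)


# ---------------------------------------------------------------------------
# expensive session fixtures (single training runs reused by several tests)

@pytest.fixture(scope="session")
def smoke_benchmark():
    return synth_benchmark(SMOKE_BENCHMARK, seed=11)


@pytest.fixture(scope="session")
def smoke_training(smoke_benchmark):
    """One full 10-epoch tiny-config training run on the clean planted
    benchmark, with its random-AUPR baseline."""
    result = train_on_benchmark(smoke_benchmark, g_p=0.2, seed=3)
    return {
        "result": result,
        "baseline": random_baseline_aupr(smoke_benchmark.val),
        "benchmark": smoke_benchmark,
    }


@pytest.fixture(scope="session")
def cosup_results():
    """The 5-seed with/without co-supervision comparison under planted
    label noise (the expensive fixture of the suite)."""
    return cosupervision_comparison(COSUP_BENCHMARK, seeds=(0, 1, 2, 3, 4))


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A fast benchmark for plumbing tests (no training quality needed)."""
    cfg = BenchmarkConfig(n_nodes=30, mean_degree=2.2, hub_fraction=0.0,
                          community_count=2, seq_length_range=(20, 40),
                          negative_ratio=5)
    return synth_benchmark(cfg, seed=5)


@pytest.fixture(scope="session")
def tiny_embeddings(tiny_benchmark):
    return embed_benchmark(tiny_benchmark)
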