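"""Shared fixtures and independent oracle implementations.

The oracles here (plain-dict BFS, exhaustive Steiner-tree search) are kept
deliberately free of networkx so they can cross-check the package's
graph-library-backed code paths.
"""

from __future__ import annotations

import itertools
from collections import deque

import pytest

from pathbench import InteractionNetwork, generate_synthetic_network


def net_from_edges(edges, nodes=(), name="test"):
    return InteractionNetwork.from_edges(edges, nodes=nodes, name=name)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def bfs_distances(net: InteractionNetwork, source: str) -> dict[str, int]:
    """Hop distances from ``source`` by a hand-rolled queue BFS."""
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for u, v in net.edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nb in adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist


def oracle_average_pairwise_distance(net: InteractionNetwork, members) -> float:
    """Mean pairwise hop distance via the independent BFS."""
    members = sorted(members)
    total, pairs = 0, 0
    for i, u in enumerate(members[:-1]):
        dist = bfs_distances(net, u)
        for v in members[i + 1 :]:
            total += dist[v]
            pairs += 1
    return total / pairs


def exact_steiner_edges(net: InteractionNetwork, terminals) -> int:
    """Minimum edge count of a connected subgraph spanning the terminals.

    Any connected subgraph containing a node set S has a spanning tree with
    |S| - 1 edges, so the optimum is min over supersets S of the terminals
    with connected induced subgraph of |S| - 1. Exponential; small graphs
    only.
    """
    terminals = set(terminals)
    if len(terminals) == 1:
        return 0
    others = sorted(net.nodes - terminals)

    def connected(subset: set[str]) -> bool:
        start = next(iter(subset))
        seen = {start}
        queue = deque([start])
        adj = net.graph.adj
        while queue:
            node = queue.popleft()
            for nb in adj[node]:
                if nb in subset and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        return seen == subset

    for extra in range(len(others) + 1):
        for combo in itertools.combinations(others, extra):
            subset = terminals | set(combo)
            if connected(subset):
                return len(subset) - 1
    raise ValueError("terminals are not connected in this graph")


# ---------------------------------------------------------------------------
# Graph fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def path5():
    """Path a-b-c-d-e."""
    return net_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def cycle6():
    nodes = [f"v{i}" for i in range(6)]
    return net_from_edges([(nodes[i], nodes[(i + 1) % 6]) for i in range(6)])


@pytest.fixture
def complete10():
    nodes = [f"n{i}" for i in range(10)]
    return net_from_edges(
        [(u, v) for u, v in itertools.combinations(nodes, 2)]
    )


@pytest.fixture
def star50():
    """Hub-and-spoke K(1, 50); hub is 'hub'."""
    return net_from_edges([("hub", f"leaf{i:02d}") for i in range(50)])


@pytest.fixture
def two_components():
    """A 5-node path and a disjoint 3-node triangle."""
    return net_from_edges(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
         ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture(scope="session")
def ba500():
    """The 500-node preferential-attachment network used in larger checks."""
    return generate_synthetic_network("preferential_attachment", 500, seed=42)
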