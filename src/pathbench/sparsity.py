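"""Sparsity metrics: how an FG set is distributed over the network.

Three measures characterise the spatial distribution of a foreground set:

* **Global FG proximity** — the number of edges of a (2-approximate) minimum
  Steiner tree covering the FG nodes: the smallest connected structure in
  the network that touches every FG gene. Lower means more compact.
* **Global FG connectivity** — mean degree of the FG nodes in the *full*
  network (not the induced subgraph): how hub-like the FG genes are.
* **Local FG density** — edge density of the FG-induced subgraph,
  |E(FG)| / C(|FG|, 2): how interconnected the FG genes are among themselves.

The average pairwise shortest-path distance is reported alongside, since it
is the dial the AVD_k generator turns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import networkx as nx
from networkx.algorithms.approximation import steiner_tree

from .graph_io import InteractionNetwork
from .fg_selection import average_pairwise_distance

__all__ = [
    "SparsityReport",
    "global_fg_proximity",
    "global_fg_connectivity",
    "local_fg_density",
    "sparsity_report",
]


@dataclass(frozen=True)
class SparsityReport:
    global_proximity: float
    global_connectivity: float
    local_density: float
    avg_pairwise_distance: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _check_fg(net: InteractionNetwork, fg: Iterable[str]) -> list[str]:
    members = sorted(set(fg))
    if not members:
        raise ValueError("FG set is empty")
    missing = [m for m in members if m not in net]
    if missing:
        raise ValueError(f"FG nodes not in network: {missing[:5]}")
    return members


def global_fg_proximity(net: InteractionNetwork, fg: Iterable[str]) -> float:
    """Edge count of an approximate minimum Steiner tree spanning the FG set.

    Uses the metric-closure 2-approximation (Kou et al.): build the complete
    graph on FG weighted by pairwise shortest-path distances, take its
    minimum spanning tree, expand each MST edge back into a shortest path and
    span the union. The result is at most twice the optimum. A single FG
    node needs no tree (0); a disconnected FG pair is an error.
    """
    members = _check_fg(net, fg)
    if len(members) == 1:
        return 0.0
    comp = nx.node_connected_component(net.graph, members[0])
    outside = [m for m in members if m not in comp]
    if outside:
        raise ValueError(
            f"FG nodes {outside[:5]} are disconnected from {members[0]!r}; "
            "the Steiner tree is undefined"
        )
    tree = steiner_tree(net.graph, members, method="kou")
    return float(tree.number_of_edges())


def global_fg_connectivity(net: InteractionNetwork, fg: Iterable[str]) -> float:
    """Mean degree of the FG nodes, measured in the full network."""
    members = _check_fg(net, fg)
    return sum(net.degree(m) for m in members) / len(members)


def local_fg_density(net: InteractionNetwork, fg: Iterable[str]) -> float:
    """Edge density of the FG-induced subgraph, in [0, 1].

    Undefined (an error) for fewer than two FG nodes, so degenerate
    configurations surface early instead of silently scoring 0.
    """
    members = _check_fg(net, fg)
    if len(members) < 2:
        raise ValueError("local FG density needs at least two FG nodes")
    induced_edges = net.graph.subgraph(members).number_of_edges()
    return induced_edges / math.comb(len(members), 2)


def sparsity_report(net: InteractionNetwork, fg: Iterable[str]) -> SparsityReport:
    """All three sparsity measures plus the average pairwise distance."""
    members = _check_fg(net, fg)
    return SparsityReport(
        global_proximity=global_fg_proximity(net, members),
        global_connectivity=global_fg_connectivity(net, members),
        local_density=local_fg_density(net, members),
        avg_pairwise_distance=average_pairwise_distance(net, members),
    )
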