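"""Interaction-network container, edge-list I/O and synthetic network generators.

Molecular interaction networks (protein-protein interaction databases such as
HPRD or I2D) are modelled as undirected simple graphs: a set of vertices V
(genes/proteins, opaque string identifiers) and a set of edges E. Edge
direction, interaction type and confidence scores present in source files are
deliberately ignored -- all downstream algorithms use topology only.
"""

from __future__ import annotations

import logging
import random
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "read_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "generate_synthetic_network",
    "EdgeListParseError",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


class InteractionNetwork:
    """An undirected simple graph of molecular interactions.

    Invariants enforced at construction:

    * no self-loops, no parallel edges (each unordered pair at most once);
    * every edge endpoint is a declared node;
    * node identifiers are unique, non-empty strings, taken verbatim
      (case-sensitive, no gene-symbol normalisation).

    Parameters
    ----------
    graph:
        A :class:`networkx.Graph`; held by reference, callers should not
        mutate it afterwards.
    name:
        Free-text label used in logs and provenance records.
    """

    __slots__ = ("_g", "name")

    def __init__(self, graph: nx.Graph, name: str = "") -> None:
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("interaction networks are undirected simple graphs")
        for node in graph.nodes:
            if not isinstance(node, str) or not node:
                raise ValueError(
                    f"node identifiers must be non-empty strings, got {node!r}"
                )
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {loops[:5]}")
        self._g = graph
        self.name = name

    # -- alternative constructors -------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        name: str = "",
    ) -> "InteractionNetwork":
        """Build a network from unordered node pairs, deduplicating silently."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        g.remove_edges_from(nx.selfloop_edges(g))
        return cls(g, name=name)

    # -- views ---------------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (read-only by convention)."""
        return self._g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """Edges as canonical (min, max) pairs."""
        return frozenset((u, v) if u <= v else (v, u) for u, v in self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    def neighbors(self, node: str) -> Iterator[str]:
        return self._g.neighbors(node)

    def sorted_nodes(self) -> list[str]:
        """Nodes in lexicographic order; the canonical iteration order."""
        return sorted(self._g.nodes)

    def induced_subgraph(self, nodes: Iterable[str], name: str = "") -> "InteractionNetwork":
        sub = self._g.subgraph(nodes).copy()
        return InteractionNetwork(sub, name=name or self.name)

    def __len__(self) -> int:
        return self.n_nodes

    def __contains__(self, node: object) -> bool:
        return node in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:  # pragma: no cover - identity semantics suffice
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return f"<InteractionNetwork{label}: {self.n_nodes} nodes, {self.n_edges} edges>"


def _infer_format(path: Path) -> str:
    return "sif" if path.suffix.lower() == ".sif" else "tsv"


def read_edge_list(
    path: str | Path, format: str | None = None, name: str | None = None
) -> InteractionNetwork:
    """Read an interaction network from a TSV or SIF edge list.

    TSV lines name the two endpoints in columns 1-2 (tab- or
    whitespace-delimited); SIF lines are ``node1 type node2 [node4 ...]``
    where column 2 (the interaction type) is ignored and, following the SIF
    convention, every column from 3 onwards is a target of column 1. Lines
    starting with ``#`` and blank lines are skipped. Self-loops and duplicate
    edges (including reversed duplicates) are dropped; the number of dropped
    records is logged.

    Raises
    ------
    EdgeListParseError
        If a non-comment line has fewer columns than the format requires, or
        the file contains no edges at all.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}")

    g = nx.Graph()
    dropped_loops = 0
    dropped_dups = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if fmt == "tsv":
                if len(cols) < 2:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: expected at least 2 columns, got {len(cols)}"
                    )
                pairs = [(cols[0], cols[1])]
            else:
                if len(cols) < 3:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: SIF line needs at least 3 columns, got {len(cols)}"
                    )
                pairs = [(cols[0], t) for t in cols[2:]]
            for u, v in pairs:
                if u == v:
                    dropped_loops += 1
                elif g.has_edge(u, v):
                    dropped_dups += 1
                else:
                    g.add_edge(u, v)

    if g.number_of_edges() == 0:
        raise EdgeListParseError(f"{path}: no edges found")
    if dropped_loops or dropped_dups:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge record(s)",
            path,
            dropped_loops,
            dropped_dups,
        )
    return InteractionNetwork(g, name=name if name is not None else path.stem)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Write a canonical TSV edge list.

    Endpoints are sorted lexicographically within each line and lines are
    sorted, so equal networks serialise to byte-identical files. Isolated
    nodes are listed in a trailing comment block so the round trip preserves
    the node set exactly.
    """
    path = Path(path)
    lines = sorted("\t".join(e) for e in net.edges)
    isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
    with path.open("w") as fh:
        for line in lines:
            fh.write(line + "\n")
        for node in isolated:
            fh.write(f"#node\t{node}\n")


def read_canonical_edge_list(path: str | Path, name: str | None = None) -> InteractionNetwork:
    """Read a TSV written by :func:`write_edge_list`, restoring isolated nodes."""
    path = Path(path)
    isolated = []
    with path.open() as fh:
        for raw in fh:
            if raw.startswith("#node\t"):
                isolated.append(raw.rstrip("\n").split("\t")[1])
    net = read_edge_list(path, format="tsv", name=name)
    if isolated:
        g = net.graph.copy()
        g.add_nodes_from(isolated)
        net = InteractionNetwork(g, name=net.name)
    return net


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest connected component.

    Ties between equal-sized components are broken in favour of the component
    containing the lexicographically smallest node, so the result is
    deterministic. Idempotent on connected graphs.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    sizes: dict[int, list[set[str]]] = {}
    for comp in nx.connected_components(net.graph):
        sizes.setdefault(len(comp), []).append(comp)
    max_size = max(sizes)
    best = min(sizes[max_size], key=min)
    if len(best) < net.n_nodes:
        logger.info(
            "restricting %r to largest connected component: %d of %d nodes kept",
            net.name or "network",
            len(best),
            net.n_nodes,
        )
    return net.induced_subgraph(best)


_MAX_CONNECT_ATTEMPTS = 50


def generate_synthetic_network(
    model: str,
    n_nodes: int,
    model_params: Mapping[str, object] | None = None,
    seed: int = 0,
) -> InteractionNetwork:
    """Generate a connected synthetic interaction network.

    Models
    ------
    ``preferential_attachment``
        Barabási–Albert graph; ``m`` (edges per new node, default 2) controls
        density. Scale-free degree distributions make this the standard
        stand-in for protein-interaction topology.
    ``ring_lattice``
        Watts–Strogatz ring with ``degree`` neighbours (default 2) and
        optional ``rewire_p`` (default 0, i.e. a pure lattice; ``degree=2``
        yields the cycle C_n).
    ``erdos_renyi``
        G(n, p) with ``p`` (default 0.1); regenerated with derived seeds until
        connected, up to a bounded number of attempts.

    The same ``seed`` always yields an identical graph. Node identifiers are
    ``v000``-style zero-padded strings.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    params = dict(model_params or {})
    rng = random.Random(seed)
    width = max(3, len(str(n_nodes - 1)))

    def relabel(g: nx.Graph) -> nx.Graph:
        mapping = {i: f"v{i:0{width}d}" for i in g.nodes}
        return nx.relabel_nodes(g, mapping)

    for attempt in range(_MAX_CONNECT_ATTEMPTS):
        sub_seed = seed if attempt == 0 else rng.randrange(2**31)
        if model == "preferential_attachment":
            m = int(params.get("m", 2))
            g = nx.barabasi_albert_graph(n_nodes, m, seed=sub_seed)
        elif model == "ring_lattice":
            degree = int(params.get("degree", 2))
            rewire_p = float(params.get("rewire_p", 0.0))
            g = nx.watts_strogatz_graph(n_nodes, degree, rewire_p, seed=sub_seed)
        elif model == "erdos_renyi":
            p = float(params.get("p", 0.1))
            g = nx.gnp_random_graph(n_nodes, p, seed=sub_seed)
        else:
            raise ValueError(f"unknown synthetic network model {model!r}")
        if nx.is_connected(g):
            name = f"{model}_n{n_nodes}_seed{seed}"
            return InteractionNetwork(relabel(g), name=name)

    raise RuntimeError(
        f"could not generate a connected {model} graph with n={n_nodes}, "
        f"params={params} after {_MAX_CONNECT_ATTEMPTS} attempts"
    )
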