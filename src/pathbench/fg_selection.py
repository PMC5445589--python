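"""Foreground/background node selection for synthetic gold standards.

A gold standard for evaluating de novo pathway enrichment is a partition of
the network's vertices into foreground (FG) genes -- the "hidden" active
module the tools are supposed to recover -- and background (BG) genes.
Two selection algorithms are provided:

* **Seed-and-extend (SAE)**: grow a connected node set breadth-first from a
  uniformly random seed until it has ``n`` nodes. FG sets are maximally
  compact (always connected).
* **Average-distance-k (AVD_k)**: select ``n`` nodes whose average pairwise
  shortest-path distance is ``k ± alpha``, so the *sparsity* of the FG set is
  a controllable dial. Exact selection is NP-complete; a restarting greedy
  heuristic is used, with a bounded exhaustive enumerator as a small-instance
  oracle.

Distances are unweighted hop counts throughout.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .graph_io import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandardSplit",
    "seed_and_extend",
    "avd_k_greedy",
    "avd_k_exhaustive",
    "average_pairwise_distance",
    "generate_fg_collection",
    "AvdKInfeasibleError",
]

#: Default tolerance around the target average distance k.
DEFAULT_ALPHA = 1.0
#: Default number of greedy restarts before declaring infeasibility.
DEFAULT_MAX_RESTARTS = 50


class AvdKInfeasibleError(RuntimeError):
    """No node set with the requested average pairwise distance was found.

    Attributes
    ----------
    best_average:
        The achieved average pairwise distance closest to the target across
        all restarts (``None`` if no complete candidate set was ever built).
    """

    def __init__(self, message: str, best_average: float | None = None) -> None:
        super().__init__(message)
        self.best_average = best_average


@dataclass(frozen=True)
class GoldStandardSplit:
    """A partition of network nodes into foreground and background.

    ``fg_nodes`` and ``bg_nodes`` are disjoint and together cover the source
    network's vertex set. ``achieved_avg_distance`` records the realised
    average pairwise shortest-path distance of the FG set (AVD_k only).
    """

    fg_nodes: frozenset[str]
    bg_nodes: frozenset[str]
    generator: str  # "SAE" or "AVDk"
    params: dict = field(default_factory=dict)
    seed: int = 0
    achieved_avg_distance: float | None = None

    def __post_init__(self) -> None:
        if not self.fg_nodes:
            raise ValueError("foreground set must be non-empty")
        overlap = self.fg_nodes & self.bg_nodes
        if overlap:
            raise ValueError(f"FG and BG overlap: {sorted(overlap)[:5]}")

    @property
    def all_nodes(self) -> frozenset[str]:
        return self.fg_nodes | self.bg_nodes

    @property
    def fg_size(self) -> int:
        return len(self.fg_nodes)

    def matches_network(self, net: InteractionNetwork) -> bool:
        return self.all_nodes == net.nodes

    # -- serialisation -------------------------------------------------------

    def to_files(self, directory: str | Path) -> None:
        """Write ``fg.txt``, ``bg.txt`` (one node per line, sorted) and a
        ``provenance.json`` sidecar recording how the split was generated."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "fg.txt").write_text("".join(f"{n}\n" for n in sorted(self.fg_nodes)))
        (directory / "bg.txt").write_text("".join(f"{n}\n" for n in sorted(self.bg_nodes)))
        provenance = {
            "generator": self.generator,
            "params": self.params,
            "seed": self.seed,
            "achieved_avg_distance": self.achieved_avg_distance,
        }
        (directory / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")

    @classmethod
    def from_files(cls, directory: str | Path) -> "GoldStandardSplit":
        directory = Path(directory)
        fg = frozenset((directory / "fg.txt").read_text().split())
        bg = frozenset((directory / "bg.txt").read_text().split())
        prov_path = directory / "provenance.json"
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(
            fg_nodes=fg,
            bg_nodes=bg,
            generator=prov.get("generator", "unknown"),
            params=prov.get("params", {}),
            seed=prov.get("seed", 0),
            achieved_avg_distance=prov.get("achieved_avg_distance"),
        )


def _split_from_fg(
    net: InteractionNetwork,
    fg: frozenset[str],
    generator: str,
    params: dict,
    seed: int,
    achieved: float | None = None,
) -> GoldStandardSplit:
    return GoldStandardSplit(
        fg_nodes=fg,
        bg_nodes=frozenset(net.nodes - fg),
        generator=generator,
        params=params,
        seed=seed,
        achieved_avg_distance=achieved,
    )


# ---------------------------------------------------------------------------
# Seed and extend
# ---------------------------------------------------------------------------


def seed_and_extend(net: InteractionNetwork, n: int, seed: int) -> GoldStandardSplit:
    """Grow a connected FG set of target size ``n`` from a random seed node.

    The seed node is drawn uniformly at random; the set is then expanded by
    whole neighbourhood layers. If adding the next layer would overshoot
    ``n``, exactly enough frontier nodes are sampled uniformly at random to
    reach ``n``. If the frontier empties first (the seed's component is
    smaller than ``n``), the FG set is the whole component and the shortfall
    is logged as a warning.
    """
    if n < 1:
        raise ValueError("target FG size n must be >= 1")
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    rng = random.Random(seed)
    g = net.graph
    start = rng.choice(net.sorted_nodes())

    fg: set[str] = {start}
    while len(fg) < n:
        frontier = sorted({nb for node in fg for nb in g.neighbors(node)} - fg)
        if not frontier:
            logger.warning(
                "seed-and-extend stalled at %d of %d nodes (seed node %r is in a "
                "component of size %d)",
                len(fg),
                n,
                start,
                len(fg),
            )
            break
        need = n - len(fg)
        if len(frontier) <= need:
            fg.update(frontier)
        else:
            fg.update(rng.sample(frontier, need))

    return _split_from_fg(
        net, frozenset(fg), "SAE", {"n": n, "achieved_n": len(fg)}, seed
    )


# ---------------------------------------------------------------------------
# Average pairwise distance
# ---------------------------------------------------------------------------


def average_pairwise_distance(net: InteractionNetwork, nodes) -> float:
    """Mean unweighted shortest-path distance over all unordered node pairs.

    Raises :class:`ValueError` if ``nodes`` has fewer than two members or any
    pair is disconnected (infinite distance).
    """
    members = sorted(nodes)
    if len(members) < 2:
        raise ValueError("need at least two nodes for an average pairwise distance")
    missing = [m for m in members if m not in net]
    if missing:
        raise ValueError(f"nodes not in network: {missing[:5]}")
    total = 0
    n_pairs = 0
    for i, source in enumerate(members[:-1]):
        dist = nx.single_source_shortest_path_length(net.graph, source)
        for target in members[i + 1 :]:
            if target not in dist:
                raise ValueError(
                    f"nodes {source!r} and {target!r} are disconnected "
                    "(infinite distance)"
                )
            total += dist[target]
            n_pairs += 1
    return total / n_pairs


# ---------------------------------------------------------------------------
# AVD_k greedy heuristic
# ---------------------------------------------------------------------------


def avd_k_greedy(
    net: InteractionNetwork,
    n: int,
    k: float,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    max_restarts: int = DEFAULT_MAX_RESTARTS,
) -> GoldStandardSplit:
    """Select ``n`` nodes with average pairwise distance in ``[k-alpha, k+alpha]``.

    Restarting greedy heuristic: from a random start node, repeatedly add the
    candidate ``c`` (from the start's connected component, so all distances
    stay finite) minimising the deviation of the running pair-distance sum
    from its target ``k * C(|W|+1, 2)``, breaking ties uniformly at random.
    A completed set is accepted if its average lies within the tolerance
    band; otherwise the heuristic restarts from a new random node, up to
    ``max_restarts`` attempts.

    Raises
    ------
    AvdKInfeasibleError
        If no accepted set is found within ``max_restarts`` restarts; the
        error carries the best achieved average for diagnosis.
    """
    if n < 2:
        raise ValueError("target FG size n must be >= 2 for AVD_k")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if max_restarts < 1:
        raise ValueError("max_restarts must be >= 1")

    rng = random.Random(seed)
    g = net.graph
    all_nodes = net.sorted_nodes()
    components = {frozenset(c) for c in nx.connected_components(g)}
    comp_of = {node: comp for comp in components for node in comp}
    eligible_starts = [v for v in all_nodes if len(comp_of[v]) >= n]
    if not eligible_starts:
        raise AvdKInfeasibleError(
            f"no connected component has {n} nodes", best_average=None
        )

    n_pairs = math.comb(n, 2)
    lo, hi = k - alpha, k + alpha
    best_avg: float | None = None

    for _ in range(max_restarts):
        start = rng.choice(eligible_starts)
        members = [start]
        # dist_sum[c] = sum of d(c, w) over current members w; its keys are the
        # BFS-reachable nodes, i.e. exactly the start's component minus W

        dist_sum = dict(nx.single_source_shortest_path_length(g, start))
        del dist_sum[start]
        pair_sum = 0.0

        while len(members) < n:
            target_sum = k * math.comb(len(members) + 1, 2)
            best_score = math.inf
            best_cands: list[str] = []
            for cand in dist_sum:
                score = abs(target_sum - (pair_sum + dist_sum[cand]))
                if score < best_score - 1e-12:
                    best_score = score
                    best_cands = [cand]
                elif score <= best_score + 1e-12:
                    best_cands.append(cand)
            chosen = rng.choice(sorted(best_cands))
            pair_sum += dist_sum.pop(chosen)
            members.append(chosen)
            for node, d in nx.single_source_shortest_path_length(g, chosen).items():
                if node in dist_sum:
                    dist_sum[node] += d

        avg = pair_sum / n_pairs
        if best_avg is None or abs(avg - k) < abs(best_avg - k):
            best_avg = avg
        if lo <= avg <= hi:
            return _split_from_fg(
                net,
                frozenset(members),
                "AVDk",
                {"n": n, "k": k, "alpha": alpha},
                seed,
                achieved=avg,
            )

    raise AvdKInfeasibleError(
        f"AVD_k infeasible after {max_restarts} restarts "
        f"(n={n}, k={k}, alpha={alpha}); best achieved average {best_avg:.3f}",
        best_average=best_avg,
    )


# ---------------------------------------------------------------------------
# AVD_k exhaustive oracle
# ---------------------------------------------------------------------------

_ENUMERATION_GUARD = 10**6


def avd_k_exhaustive(
    net: InteractionNetwork, n: int, k: float, alpha: float = DEFAULT_ALPHA
) -> set[frozenset[str]]:
    """Enumerate *all* size-``n`` node sets with average distance in the band.

    Exact by construction, therefore exponential: guarded to at most 10^6
    candidate subsets. Intended as the ground-truth oracle for validating the
    greedy heuristic on small graphs; use :func:`avd_k_greedy` on anything
    larger. Subsets containing a disconnected pair are excluded (their
    average distance is infinite).
    """
    if n < 2:
        raise ValueError("subset size n must be >= 2")
    n_subsets = math.comb(net.n_nodes, n)
    if n_subsets > _ENUMERATION_GUARD:
        raise ValueError(
            f"C({net.n_nodes}, {n}) = {n_subsets} subsets exceeds the enumeration "
            f"guard of {_ENUMERATION_GUARD}; use avd_k_greedy instead"
        )
    dist = dict(nx.all_pairs_shortest_path_length(net.graph))
    lo, hi = k - alpha, k + alpha
    n_pairs = math.comb(n, 2)
    solutions: set[frozenset[str]] = set()
    for combo in itertools.combinations(net.sorted_nodes(), n):
        total = 0
        feasible = True
        for u, v in itertools.combinations(combo, 2):
            d = dist[u].get(v)
            if d is None:
                feasible = False
                break
            total += d
        if feasible and lo <= total / n_pairs <= hi:
            solutions.add(frozenset(combo))
    return solutions


# ---------------------------------------------------------------------------
# Batch generation
# ---------------------------------------------------------------------------


def generate_fg_collection(
    net: InteractionNetwork,
    count: int,
    generator: str,
    params: dict,
    seed: int,
) -> list[GoldStandardSplit]:
    """Generate a collection of gold-standard splits with derived seeds.

    Split ``i`` uses seed ``seed + i``, so the collection is reproducible and
    individual members can be regenerated in isolation. Duplicate FG sets are
    permitted but counted and logged. Individual infeasible slots (AVD_k) are
    logged and skipped; if more than half of the slots fail, the whole
    collection is aborted.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if generator not in ("SAE", "AVDk"):
        raise ValueError(f"unknown FG generator {generator!r}")

    splits: list[GoldStandardSplit] = []
    failures = 0
    for i in range(count):
        sub_seed = seed + i
        try:
            if generator == "SAE":
                split = seed_and_extend(net, n=int(params["n"]), seed=sub_seed)
            else:
                split = avd_k_greedy(
                    net,
                    n=int(params["n"]),
                    k=float(params["k"]),
                    alpha=float(params.get("alpha", DEFAULT_ALPHA)),
                    seed=sub_seed,
                    max_restarts=int(params.get("max_restarts", DEFAULT_MAX_RESTARTS)),
                )
        except AvdKInfeasibleError as exc:
            failures += 1
            logger.warning("FG slot %d failed: %s", i, exc)
            continue
        splits.append(split)

    if failures > count / 2:
        raise RuntimeError(
            f"{failures} of {count} FG generations failed; parameters are "
            "likely infeasible for this network"
        )
    distinct = len({s.fg_nodes for s in splits})
    if distinct < len(splits):
        logger.info(
            "FG collection contains %d duplicate set(s) among %d splits",
            len(splits) - distinct,
            len(splits),
        )
    return splits
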