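"""Method adapters: the boundary between the harness and enrichment tools.

De novo pathway enrichment tools (BioNet, KeyPathwayMiner, GXNA, ...) are
external programs with wildly different interfaces. The harness talks to all
of them through one contract: given a network edge list, an expression
matrix, a per-gene statistics table and a JSON parameter blob, produce a
flat list of predicted node IDs. External tools are wrapped as subprocesses;
two built-in baselines ship for testing and as floor/reference methods:

* ``top_n_differential`` — the n genes with the smallest p-values, ignoring
  topology entirely (what a plain differential-expression cutoff would do);
* ``greedy_module`` — seed at the most significant gene and repeatedly
  absorb the adjacent gene with the smallest p-value until the module has n
  nodes (a minimal aggregate-score method; its output is connected by
  construction).
"""

from __future__ import annotations

import abc
import json
import logging
import shlex
import subprocess
import tempfile
from pathlib import Path
from typing import Mapping

import pandas as pd

from .graph_io import InteractionNetwork, write_edge_list
from .expression_sim import ExpressionDataset, write_differential_stats

logger = logging.getLogger(__name__)

__all__ = [
    "MethodAdapter",
    "TopNDifferential",
    "GreedyModule",
    "ExternalCommandAdapter",
    "AdapterError",
    "get_builtin_adapter",
    "BUILTIN_ADAPTERS",
]


class AdapterError(RuntimeError):
    """An adapter failed to produce a usable prediction.

    ``log`` carries the captured stdout/stderr of external tools.
    """

    def __init__(self, message: str, log: str = "") -> None:
        super().__init__(message)
        self.log = log


class MethodAdapter(abc.ABC):
    """Contract: turn (network, expression, statistics, params) into node IDs."""

    name: str = "adapter"

    @abc.abstractmethod
    def predict(
        self,
        net: InteractionNetwork,
        dataset: ExpressionDataset,
        stats: pd.DataFrame,
        params: Mapping[str, object],
    ) -> set[str]:
        """Return the predicted module as a set of node identifiers."""


class TopNDifferential(MethodAdapter):
    """Baseline: the ``n`` genes with the smallest raw p-values (no topology).

    Ties are broken by gene ID so the prediction is deterministic.
    """

    name = "top_n_differential"

    def predict(self, net, dataset, stats, params):
        n = int(params.get("n", 20))
        if n < 1:
            raise AdapterError("top_n_differential needs n >= 1")
        order = sorted(zip(stats["p"], stats.index))
        return {gene for _, gene in order[:n]}


class GreedyModule(MethodAdapter):
    """Baseline: grow a connected module greedily by p-value.

    Seeds at the most significant gene and repeatedly adds the neighbouring
    gene with the smallest p-value until the module has ``n`` nodes or no
    frontier remains. Ties break by gene ID; output induces a connected
    subgraph by construction.
    """

    name = "greedy_module"

    def predict(self, net, dataset, stats, params):
        n = int(params.get("n", 20))
        if n < 1:
            raise AdapterError("greedy_module needs n >= 1")
        by_gene = stats["p"]
        seed = min(by_gene.index, key=lambda g: (by_gene[g], g))
        module = {seed}
        g = net.graph
        while len(module) < n:
            frontier = {nb for node in module for nb in g.neighbors(node)} - module
            if not frontier:
                break
            module.add(min(frontier, key=lambda c: (by_gene[c], c)))
        return module


class ExternalCommandAdapter(MethodAdapter):
    """Wrap an external enrichment tool as a subprocess.

    The command template may reference ``{network}`` (edge-list TSV),
    ``{expression}`` (matrix TSV), ``{labels}`` (sample-class TSV),
    ``{stats}`` (per-gene statistics TSV), ``{params}`` (JSON file with the
    internal-parameter values) and ``{out}``. If ``{out}`` appears, the tool
    must write one node ID per line to that file; otherwise node IDs are read
    from stdout. A nonzero exit status or unparseable output raises
    :class:`AdapterError` carrying the captured log.
    """

    def __init__(self, name: str, command: str, timeout: float | None = None) -> None:
        self.name = name
        self.command = command
        self.timeout = timeout

    def predict(self, net, dataset, stats, params):
        with tempfile.TemporaryDirectory(prefix=f"pathbench_{self.name}_") as tmp:
            tmpdir = Path(tmp)
            paths = {
                "network": tmpdir / "network.tsv",
                "expression": tmpdir / "expression.tsv",
                "labels": tmpdir / "labels.tsv",
                "stats": tmpdir / "stats.tsv",
                "params": tmpdir / "params.json",
                "out": tmpdir / "prediction.txt",
            }
            write_edge_list(net, paths["network"])
            dataset.to_tsv(paths["expression"], paths["labels"])
            write_differential_stats(stats, paths["stats"])
            paths["params"].write_text(json.dumps(dict(params)) + "\n")

            argv = [
                part.format(**{k: str(v) for k, v in paths.items()})
                for part in shlex.split(self.command)
            ]
            uses_out_file = "{out}" in self.command
            try:
                proc = subprocess.run(
                    argv, capture_output=True, text=True, timeout=self.timeout
                )
            except subprocess.TimeoutExpired as exc:
                raise AdapterError(f"{self.name}: timed out after {self.timeout}s") from exc
            log = f"--- stdout ---\n{proc.stdout}\n--- stderr ---\n{proc.stderr}"
            if proc.returncode != 0:
                raise AdapterError(
                    f"{self.name}: exit status {proc.returncode}", log=log
                )
            if uses_out_file:
                if not paths["out"].exists():
                    raise AdapterError(f"{self.name}: no output file written", log=log)
                text = paths["out"].read_text()
            else:
                text = proc.stdout
            nodes = {line.strip() for line in text.splitlines() if line.strip()}
            if not nodes:
                logger.warning("%s returned an empty prediction", self.name)
            return nodes


BUILTIN_ADAPTERS: dict[str, type[MethodAdapter]] = {
    TopNDifferential.name: TopNDifferential,
    GreedyModule.name: GreedyModule,
}


def get_builtin_adapter(name: str) -> MethodAdapter:
    try:
        return BUILTIN_ADAPTERS[name]()
    except KeyError:
        raise ValueError(
            f"unknown builtin adapter {name!r}; available: {sorted(BUILTIN_ADAPTERS)}"
        ) from None
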