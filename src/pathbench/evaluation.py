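"""Scoring predictions against gold standards and sweeping parameter grids.

Evaluation is node-level classification with the foreground set as the
positive class: a predicted node is a true positive if it is an FG gene,
a false positive if it is BG; missed FG genes are false negatives.
Performance is summarised by precision, recall and their harmonic mean, the
F-measure (F1). Predicted edges are ignored -- only the proportion of
relevant (FG) versus irrelevant (BG) nodes matters, and there is no partial
credit for nodes merely near the foreground.

The benchmark runner sweeps the full Cartesian product of gold-standard
splits x simulation configurations x adapters x internal-parameter (IP)
values, producing one long-format row per run; adapter failures are
recorded, never fatal.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph_io import InteractionNetwork
from .fg_selection import GoldStandardSplit
from .expression_sim import (
    ExpressionDataset,
    SimulationConfig,
    differential_stats,
    signal_strength,
    simulate_expression,
)
from .adapters import AdapterError, MethodAdapter
from .sparsity import sparsity_report

logger = logging.getLogger(__name__)

__all__ = [
    "Prediction",
    "EvaluationResult",
    "evaluate_prediction",
    "run_method_adapter",
    "run_benchmark",
    "aggregate_results",
]


@dataclass(frozen=True)
class Prediction:
    """A predicted node set with its provenance."""

    node_ids: frozenset[str]
    method_name: str = "unknown"
    internal_params: dict = field(default_factory=dict)

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        net: InteractionNetwork | None = None,
        method_name: str | None = None,
        internal_params: Mapping[str, object] | None = None,
    ) -> "Prediction":
        """Load one node ID per line; with ``net`` given, unknown IDs are
        rejected immediately (they are rejected at evaluation time anyway)."""
        path = Path(path)
        nodes = frozenset(line.strip() for line in path.read_text().splitlines() if line.strip())
        if net is not None:
            unknown = sorted(nodes - net.nodes)
            if unknown:
                raise ValueError(
                    f"{path}: {len(unknown)} prediction node(s) not in network, "
                    f"e.g. {unknown[:5]}"
                )
        return cls(
            node_ids=nodes,
            method_name=method_name or path.stem,
            internal_params=dict(internal_params or {}),
        )


@dataclass(frozen=True)
class EvaluationResult:
    """Node-level confusion counts and derived scores for one run."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    split_generator: str = ""
    split_params: dict = field(default_factory=dict)
    method_name: str = ""
    internal_params: dict = field(default_factory=dict)


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate_prediction(
    split: GoldStandardSplit, prediction: Prediction
) -> EvaluationResult:
    """Score a prediction against a gold standard, FG as the positive class.

    Conventions: precision is 0 for an empty prediction; the F-measure is 0
    when precision and recall are both 0.
    """
    unknown = sorted(prediction.node_ids - split.all_nodes)
    if unknown:
        raise ValueError(
            f"prediction contains {len(unknown)} node(s) absent from the "
            f"network: {unknown[:5]}"
        )
    tp = len(prediction.node_ids & split.fg_nodes)
    fp = len(prediction.node_ids) - tp
    fn = len(split.fg_nodes) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    return EvaluationResult(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f_measure=_f1(precision, recall),
        split_generator=split.generator,
        split_params=dict(split.params),
        method_name=prediction.method_name,
        internal_params=dict(prediction.internal_params),
    )


def run_method_adapter(
    adapter: MethodAdapter,
    net: InteractionNetwork,
    dataset: ExpressionDataset,
    internal_params: Mapping[str, object],
    stats: pd.DataFrame | None = None,
) -> Prediction:
    """Run one adapter and validate its output against the network.

    ``stats`` (a :func:`~pathbench.expression_sim.differential_stats` table)
    may be passed in to avoid recomputation across IP values; it is derived
    from the dataset otherwise. Wall time is logged per run.
    """
    if stats is None:
        stats = differential_stats(dataset)
    start = time.perf_counter()
    nodes = adapter.predict(net, dataset, stats, dict(internal_params))
    elapsed = time.perf_counter() - start
    unknown = sorted(set(nodes) - net.nodes)
    if unknown:
        raise AdapterError(
            f"{adapter.name}: returned {len(unknown)} unknown node ID(s), "
            f"e.g. {unknown[:5]}"
        )
    logger.info("%s finished in %.3fs (%d nodes)", adapter.name, elapsed, len(nodes))
    return Prediction(
        node_ids=frozenset(nodes),
        method_name=adapter.name,
        internal_params=dict(internal_params),
    )


# ---------------------------------------------------------------------------
# Benchmark sweep
# ---------------------------------------------------------------------------

_SPLIT_SEED_STRIDE = 10_007  # per-split offset for simulation seeds


def _run_key(split_id: str, cfg: SimulationConfig, method: str, ip: Mapping) -> str:
    blob = json.dumps(
        [split_id, cfg.model, signal_strength(cfg), cfg.seed, method, dict(ip)],
        sort_keys=True,
        default=str,
    )
    return hashlib.sha1(blob.encode()).hexdigest()[:16]


def run_benchmark(
    net: InteractionNetwork,
    splits: Sequence[GoldStandardSplit],
    sim_grid: Sequence[SimulationConfig],
    adapters: Sequence[tuple[MethodAdapter, Sequence[Mapping[str, object]]]],
    out_dir: str | Path | None = None,
    compute_sparsity: bool = True,
) -> pd.DataFrame:
    """Full Cartesian sweep: splits x simulation configs x adapters x IP values.

    Expression data for split ``i`` under a grid config uses the derived seed
    ``config.seed + 10007 * i`` so every cell of the sweep is independently
    reproducible. Each run becomes one row; adapter failures are recorded in
    the ``status``/``error`` columns and do not abort the sweep.

    When ``out_dir`` is given the sweep is resumable: rows are appended to
    ``results.csv`` as they finish, a ``manifest.json`` records a hash of the
    sweep definition, and a rerun with an identical definition skips runs
    already present.
    """
    if not splits or not sim_grid or not adapters:
        raise ValueError("splits, sim_grid and adapters must all be non-empty")
    for adapter, ip_grid in adapters:
        if not ip_grid:
            raise ValueError(f"empty IP grid for adapter {adapter.name!r}")

    done: dict[str, dict] = {}
    results_path = manifest_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results_path = out_dir / "results.csv"
        manifest_path = out_dir / "manifest.json"
        sweep_hash = hashlib.sha1(
            json.dumps(
                {
                    "network": [net.n_nodes, net.n_edges, net.name],
                    "splits": sorted(sorted(s.fg_nodes) for s in splits),
                    "grid": [
                        [c.model, signal_strength(c), c.seed, c.n_cases, c.n_controls]
                        for c in sim_grid
                    ],
                    "adapters": [
                        [a.name, [dict(ip) for ip in grid]] for a, grid in adapters
                    ],
                },
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest()
        if manifest_path.exists() and results_path.exists():
            manifest = json.loads(manifest_path.read_text())
            if manifest.get("sweep_hash") == sweep_hash:
                prior = pd.read_csv(results_path)
                done = {row["run_key"]: row.to_dict() for _, row in prior.iterrows()}
                logger.info("resuming sweep: %d run(s) already recorded", len(done))
        manifest_path.write_text(
            json.dumps({"sweep_hash": sweep_hash, "n_splits": len(splits)}, indent=2)
            + "\n"
        )

    rows: list[dict] = []
    for split_idx, split in enumerate(splits):
        split_id = f"split_{split_idx:03d}"
        base = {
            "split_id": split_id,
            "generator": split.generator,
            "fg_size": split.fg_size,
            "fg_k": split.params.get("k"),
            "fg_alpha": split.params.get("alpha"),
            "achieved_avg_distance": split.achieved_avg_distance,
        }
        if compute_sparsity:
            report = sparsity_report(net, split.fg_nodes)
            base.update(
                global_proximity=report.global_proximity,
                global_connectivity=report.global_connectivity,
                local_density=report.local_density,
            )
        for cfg in sim_grid:
            run_cfg = replace(cfg, seed=cfg.seed + _SPLIT_SEED_STRIDE * split_idx)
            dataset = stats = None  # simulated lazily, once per (split, config)
            for adapter, ip_grid in adapters:
                for ip in ip_grid:
                    key = _run_key(split_id, run_cfg, adapter.name, ip)
                    if key in done:
                        rows.append(done[key])
                        continue
                    if dataset is None:
                        dataset = simulate_expression(net, split, run_cfg)
                        stats = differential_stats(dataset)
                    row = dict(
                        base,
                        run_key=key,
                        model=cfg.model,
                        signal_strength=signal_strength(cfg),
                        sim_seed=run_cfg.seed,
                        method=adapter.name,
                        ip=json.dumps(dict(ip), sort_keys=True),
                        status="ok",
                        error="",
                    )
                    try:
                        pred = run_method_adapter(
                            adapter, net, dataset, ip, stats=stats
                        )
                        res = evaluate_prediction(split, pred)
                        row.update(
                            tp=res.tp,
                            fp=res.fp,
                            fn=res.fn,
                            precision=res.precision,
                            recall=res.recall,
                            f_measure=res.f_measure,
                        )
                    except AdapterError as exc:
                        row.update(status="failed", error=str(exc))
                        logger.warning("run %s failed: %s", key, exc)
                    rows.append(row)

    table = pd.DataFrame(rows)
    if results_path is not None:
        table.to_csv(results_path, index=False)
    return table


_AGG_METRICS = ("f_measure", "precision", "recall")


def aggregate_results(
    rows: pd.DataFrame, group_by: Sequence[str]
) -> pd.DataFrame:
    """Per-group summary of F-measure, precision and recall.

    For each group: mean, median, standard deviation (population, so a
    single run reports 0 rather than NaN), lower/upper quartiles and run
    count. Failed runs are excluded.
    """
    if rows.empty:
        raise ValueError("result table is empty")
    unknown = [f for f in group_by if f not in rows.columns]
    if unknown:
        raise ValueError(f"unknown grouping field(s): {unknown}")
    ok = rows[rows.get("status", "ok") == "ok"] if "status" in rows.columns else rows
    if ok.empty:
        raise ValueError("no successful runs to aggregate")

    def _std0(x):
        return float(x.std(ddof=0))

    def _q25(x):
        return float(x.quantile(0.25))

    def _q75(x):
        return float(x.quantile(0.75))

    _std0.__name__ = "std"
    _q25.__name__ = "q25"
    _q75.__name__ = "q75"
    agg_spec = {}
    for metric in _AGG_METRICS:
        agg_spec[metric] = ["mean", "median", _std0, _q25, _q75]
    grouped = ok.groupby(list(group_by), dropna=False).agg(agg_spec)
    grouped.columns = [f"{metric}_{label}" for metric, label in grouped.columns]
    grouped["n_runs"] = ok.groupby(list(group_by), dropna=False).size()
    return grouped.reset_index()
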