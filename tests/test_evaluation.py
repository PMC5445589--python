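"""Prediction scoring, baseline adapters, benchmark sweep and aggregation."""

import json
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathbench import (
    AdapterError,
    ExternalCommandAdapter,
    GoldStandardSplit,
    GreedyModule,
    Prediction,
    SimulationConfig,
    TopNDifferential,
    aggregate_results,
    avd_k_greedy,
    differential_stats,
    evaluate_prediction,
    run_benchmark,
    run_method_adapter,
    seed_and_extend,
    simulate_expression,
)


def make_split(fg, bg):
    return GoldStandardSplit(
        fg_nodes=frozenset(fg), bg_nodes=frozenset(bg), generator="SAE"
    )


class TestEvaluatePrediction:
    def test_perfect_prediction(self):
        split = make_split("abc", "de")
        res = evaluate_prediction(split, Prediction(frozenset("abc")))
        assert (res.precision, res.recall, res.f_measure) == (1.0, 1.0, 1.0)

    def test_half_right(self):
        fg = {f"f{i}" for i in range(20)}
        bg = {f"b{i}" for i in range(80)}
        pred = frozenset(list(sorted(fg))[:10] + list(sorted(bg))[:10])
        res = evaluate_prediction(make_split(fg, bg), Prediction(pred))
        assert res.tp == 10 and res.fp == 10 and res.fn == 10
        assert res.precision == 0.5 and res.recall == 0.5 and res.f_measure == 0.5

    def test_empty_prediction_scores_zero(self):
        res = evaluate_prediction(make_split("ab", "cd"), Prediction(frozenset()))
        assert res.tp == 0 and res.f_measure == 0.0 and res.precision == 0.0

    def test_unknown_ids_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            evaluate_prediction(
                make_split("ab", "cd"), Prediction(frozenset({"a", "GHOST"}))
            )

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50)
    )
    @settings(max_examples=200, derandomize=True)
    def test_f_is_the_harmonic_mean(self, tp, fp, fn):
        """F * (precision + recall) == 2 * precision * recall for every
        reachable confusion configuration, with tp + fn = |FG| >= 1."""
        if tp + fn == 0:
            fn = 1
        fg = {f"f{i}" for i in range(tp + fn)}
        bg = {f"b{i}" for i in range(fp + 5)}
        pred = frozenset(list(sorted(fg))[:tp] + list(sorted(bg))[:fp])
        res = evaluate_prediction(make_split(fg, bg), Prediction(pred))
        assert res.tp == tp and res.fp == fp and res.fn == fn
        assert res.f_measure * (res.precision + res.recall) == pytest.approx(
            2 * res.precision * res.recall
        )
        assert res.f_measure <= max(res.precision, res.recall) + 1e-12


@pytest.fixture(scope="module")
def bench_setup(ba500):
    split = seed_and_extend(ba500, 20, seed=1)
    cfg = SimulationConfig.vm(mu_fg=2.0, seed=5)
    dataset = simulate_expression(ba500, split, cfg)
    stats = differential_stats(dataset)
    return ba500, split, dataset, stats


class TestBuiltinAdapters:
    def test_top_n_size_contract(self, bench_setup):
        net, split, dataset, stats = bench_setup
        pred = run_method_adapter(TopNDifferential(), net, dataset, {"n": 20}, stats)
        assert len(pred.node_ids) == 20

    def test_greedy_module_is_connected(self, bench_setup):
        net, split, dataset, stats = bench_setup
        pred = run_method_adapter(GreedyModule(), net, dataset, {"n": 25}, stats)
        assert len(pred.node_ids) == 25
        assert nx.is_connected(net.graph.subgraph(pred.node_ids))

    def test_strong_signal_is_recovered(self, bench_setup):
        net, split, dataset, stats = bench_setup
        for adapter in (TopNDifferential(), GreedyModule()):
            pred = run_method_adapter(adapter, net, dataset, {"n": 20}, stats)
            res = evaluate_prediction(split, pred)
            assert res.f_measure > 0.5

    def test_null_signal_matches_hypergeometric_baseline(self, ba500):
        """At signal strength 0 top-n picks are effectively random: over
        seeds, mean F approaches E[TP]/n for TP ~ Hypergeom(|V|, |FG|, n)."""
        split = seed_and_extend(ba500, 20, seed=2)
        adapter = TopNDifferential()
        n_seeds = 50
        f_values = []
        for seed in range(n_seeds):
            cfg = SimulationConfig.vm(mu_fg=0.0, mu_fgc=0.0, seed=seed)
            dataset = simulate_expression(ba500, split, cfg)
            pred = run_method_adapter(adapter, ba500, dataset, {"n": 20})
            f_values.append(evaluate_prediction(split, pred).f_measure)
        expected_f = 20 * 20 / 500 / 20  # E[TP]/|FG| = precision = recall = F
        se = np.std(f_values, ddof=1) / math.sqrt(n_seeds)
        assert np.mean(f_values) == pytest.approx(expected_f, abs=max(4 * se, 0.02))

    def test_permuted_foreground_destroys_signal(self, ba500):
        """Relabelling FG after simulation must drop the baselines to the
        random-overlap floor even at high signal strength."""
        rng = np.random.default_rng(0)
        f_values = []
        for seed in range(15):
            split = seed_and_extend(ba500, 20, seed=seed)
            cfg = SimulationConfig.vm(mu_fg=2.0, seed=seed)
            dataset = simulate_expression(ba500, split, cfg)
            shuffled_fg = frozenset(
                rng.choice(ba500.sorted_nodes(), size=20, replace=False)
            )
            shuffled = GoldStandardSplit(
                fg_nodes=shuffled_fg,
                bg_nodes=frozenset(ba500.nodes - shuffled_fg),
                generator="SAE",
            )
            pred = run_method_adapter(TopNDifferential(), ba500, dataset, {"n": 20})
            f_values.append(evaluate_prediction(shuffled, pred).f_measure)
        assert np.mean(f_values) < 0.12  # random floor is 0.04


class TestExternalAdapter:
    ECHO_FG = (
        "import json,sys\n"
        "stats=open(sys.argv[1]).read().splitlines()\n"
        "params=json.load(open(sys.argv[2]))\n"
        "genes=[l.split('\\t')[0] for l in stats[1:]]\n"
        "print('\\n'.join(genes[:int(params['n'])]))\n"
    )

    def _script(self, tmp_path, body):
        path = tmp_path / "tool.py"
        path.write_text(body)
        return path

    def test_stdout_contract(self, tmp_path, bench_setup):
        net, split, dataset, stats = bench_setup
        script = self._script(tmp_path, self.ECHO_FG)
        adapter = ExternalCommandAdapter(
            "echo_tool", f"python {script} {{stats}} {{params}}"
        )
        pred = run_method_adapter(adapter, net, dataset, {"n": 7}, stats)
        assert len(pred.node_ids) == 7
        assert pred.node_ids <= net.nodes

    def test_out_file_contract(self, tmp_path, bench_setup):
        net, split, dataset, stats = bench_setup
        body = (
            "import sys\n"
            "lines=open(sys.argv[1]).read().splitlines()[1:3]\n"
            "open(sys.argv[2],'w').write('\\n'.join(l.split('\\t')[0] for l in lines))\n"
        )
        script = self._script(tmp_path, body)
        adapter = ExternalCommandAdapter("filer", f"python {script} {{stats}} {{out}}")
        pred = run_method_adapter(adapter, net, dataset, {}, stats)
        assert len(pred.node_ids) == 2

    def test_nonzero_exit_raises_with_log(self, tmp_path, bench_setup):
        net, split, dataset, stats = bench_setup
        script = self._script(
            tmp_path, "import sys; print('boom', file=sys.stderr); sys.exit(3)"
        )
        adapter = ExternalCommandAdapter("crasher", f"python {script}")
        with pytest.raises(AdapterError, match="exit status 3") as exc:
            run_method_adapter(adapter, net, dataset, {}, stats)
        assert "boom" in exc.value.log

    def test_unknown_ids_rejected(self, tmp_path, bench_setup):
        net, split, dataset, stats = bench_setup
        script = self._script(tmp_path, "print('NOT_A_NODE')")
        adapter = ExternalCommandAdapter("alien", f"python {script}")
        with pytest.raises(AdapterError, match="unknown node"):
            run_method_adapter(adapter, net, dataset, {}, stats)


class _AlwaysFails(TopNDifferential):
    name = "always_fails"

    def predict(self, net, dataset, stats, params):
        raise AdapterError("synthetic failure for testing")


class TestRunBenchmark:
    def test_product_row_count(self, ba500):
        splits = [seed_and_extend(ba500, 10, seed=s) for s in (0, 1)]
        grid = [SimulationConfig.vm(mu_fg=s, seed=9) for s in (0.5, 2.0)]
        adapters = [(TopNDifferential(), [{"n": 5}, {"n": 10}, {"n": 20}])]
        table = run_benchmark(ba500, splits, grid, adapters, compute_sparsity=False)
        assert len(table) == 2 * 2 * 1 * 3
        assert (table["status"] == "ok").all()

    def test_rerun_identical(self, ba500):
        splits = [seed_and_extend(ba500, 10, seed=0)]
        grid = [SimulationConfig.vm(mu_fg=1.0, seed=3)]
        adapters = [(GreedyModule(), [{"n": 10}])]
        t1 = run_benchmark(ba500, splits, grid, adapters, compute_sparsity=False)
        t2 = run_benchmark(ba500, splits, grid, adapters, compute_sparsity=False)
        pd.testing.assert_frame_equal(t1, t2)

    def test_failing_adapter_is_isolated(self, ba500):
        splits = [seed_and_extend(ba500, 10, seed=0)]
        grid = [SimulationConfig.vm(mu_fg=1.0, seed=3)]
        adapters = [
            (_AlwaysFails(), [{"n": 10}]),
            (TopNDifferential(), [{"n": 10}]),
        ]
        table = run_benchmark(ba500, splits, grid, adapters, compute_sparsity=False)
        by_method = table.set_index("method")
        assert by_method.loc["always_fails", "status"] == "failed"
        assert by_method.loc["top_n_differential", "status"] == "ok"

    def test_resume_skips_completed_runs(self, tmp_path, ba500):
        splits = [seed_and_extend(ba500, 10, seed=0)]
        grid = [SimulationConfig.vm(mu_fg=1.0, seed=3)]
        adapters = [(TopNDifferential(), [{"n": 10}])]
        t1 = run_benchmark(
            ba500, splits, grid, adapters, out_dir=tmp_path, compute_sparsity=False
        )
        t2 = run_benchmark(
            ba500, splits, grid, adapters, out_dir=tmp_path, compute_sparsity=False
        )
        assert t1["run_key"].tolist() == t2["run_key"].tolist()
        assert json.loads((tmp_path / "manifest.json").read_text())["n_splits"] == 1

    def test_empty_grid_rejected(self, ba500):
        with pytest.raises(ValueError, match="non-empty"):
            run_benchmark(ba500, [], [], [])


class TestAggregateResults:
    def test_group_means(self):
        rows = pd.DataFrame(
            {
                "method": ["m", "m"],
                "f_measure": [0.5, 1.0],
                "precision": [0.5, 1.0],
                "recall": [0.5, 1.0],
            }
        )
        out = aggregate_results(rows, ["method"])
        assert out.loc[0, "f_measure_mean"] == 0.75

    def test_single_row_sd_zero(self):
        rows = pd.DataFrame(
            {"method": ["m"], "f_measure": [0.4], "precision": [0.4], "recall": [0.4]}
        )
        out = aggregate_results(rows, ["method"])
        assert out.loc[0, "f_measure_mean"] == 0.4
        assert out.loc[0, "f_measure_median"] == 0.4
        assert out.loc[0, "f_measure_std"] == 0.0

    def test_group_count(self):
        rows = pd.DataFrame(
            {
                "method": ["a", "a", "b", "b", "a", "b"],
                "signal_strength": [0, 1, 0, 1, 2, 2],
                "f_measure": [0.1] * 6,
                "precision": [0.1] * 6,
                "recall": [0.1] * 6,
            }
        )
        out = aggregate_results(rows, ["method", "signal_strength"])
        assert len(out) == 6

    def test_unknown_field_rejected(self):
        rows = pd.DataFrame({"f_measure": [1.0], "precision": [1.0], "recall": [1.0]})
        with pytest.raises(ValueError, match="unknown grouping"):
            aggregate_results(rows, ["nope"])
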