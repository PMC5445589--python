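# Methods

`pathbench` builds synthetic benchmark instances for *de novo pathway
enrichment* (active-subnetwork extraction) methods and scores predictions
against them. This note documents the models, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
conventions.

## The benchmarking model

De novo pathway enrichment tools take a large molecular interaction network
*G = (V, E)* plus per-gene experimental data and extract a sub-network
enriched in "active" genes. Because the methods are unsupervised, they can
only be evaluated against a gold standard that designates which nodes are
truly relevant. Curated disease pathways are a biased gold standard: they are
incomplete and provide no explicit set of irrelevant genes. `pathbench`
therefore *plants* the truth. The vertex set is partitioned into foreground
(FG) genes — the hidden active module — and background (BG) genes, expression
data are simulated around that partition, and a method's predicted node set
is scored by how well it recovers FG.

Two dials control problem difficulty:

* **Sparsity** — how spread out the FG nodes are over the network. Compact
  foregrounds are easy to cover with a connected module; scattered ones are
  hard.
* **Signal strength** — how separable the FG expression distribution is from
  the BG distribution.

## Foreground selection

### Seed and extend (SAE)

Pick a seed node uniformly at random and grow breadth-first, adding whole
neighbourhood layers, until the set has *n* nodes (default n = 20). If the
next layer would overshoot *n*, exactly `n − |current|` frontier nodes are
sampled uniformly at random; the already-absorbed layers are kept, which
keeps the set connected and of size exactly *n*. (The natural alternative
reading — resampling *n − 1* nodes from the neighbourhood alone — cannot
guarantee connectivity, so the frontier-sampling interpretation was adopted
and is the documented behaviour.) If the seed's component is exhausted first,
the FG set is the whole component and the shortfall is logged as a warning.
SAE foregrounds always induce a connected subgraph.

### Average-distance-k (AVD_k)

Select *W ⊆ V*, |W| = n, such that the mean unweighted shortest-path
distance over all C(n, 2) unordered pairs of *W* lies in [k − α, k + α].
The tolerance α defaults to 1, so AVD_3 produces sets with average pairwise
distance between 2 and 4. Exact selection is NP-complete; two routes are
provided:

* **Greedy heuristic** (`avd_k_greedy`): start from a random node and, while
  |W| < n, add the candidate *c* minimising
  `| k·C(|W|+1, 2) − (pair_sum(W) + Σ_{w∈W} d(c, w)) |`,
  i.e. the candidate keeping the running pair-distance sum closest to its
  target value for the grown set. Ties break uniformly at random under the
  call's seeded RNG. If the completed set misses the tolerance band the
  search restarts from a new random node, up to `max_restarts` (default 50)
  attempts, then raises an infeasibility error carrying the best achieved
  average. Candidates are restricted to the start node's connected component
  so every distance is finite. Each growth step costs one BFS plus a linear
  scan, so a full run is O(n · (|V| + |E|)). This concrete scoring rule is
  this package's design; it reproduces the published behaviour (sets landing
  in [k − α, k + α]) but other greedy formulations exist.
* **Exhaustive oracle** (`avd_k_exhaustive`): enumerate all C(|V|, n)
  subsets (guarded to ≤ 10⁶) and return exactly those inside the band. Used
  to validate the heuristic on small graphs; property tests confirm that
  every greedy solution is in the oracle's output and that the greedy finds
  a solution whenever one exists (generous restarts, |V| ≤ 14).

AVD_k foregrounds need not be connected — deliberately so, since genes
deregulated in a condition are often not directly adjacent in incomplete
interaction networks.

`generate_fg_collection` derives slot *i*'s seed as `master_seed + i`, so
collections are reproducible and members can be regenerated in isolation.
Duplicate FG sets across slots are permitted but counted and logged.

## Expression simulation

Each of the |V| genes gets one value per sample, drawn independently from a
normal distribution selected by the (gene class, sample class) cell. The
default design is 100 case and 10 control samples (110 columns).

| model | FG × case | FG × control | BG × any | signal strength |
|---|---|---|---|---|
| VM (varying mean) | N(μ_FG, v) | N(μ_FGC, v) | N(0, v) | μ_FG − μ_FGC |
| VV (varying variance) | N(μ, v_FG) | N(μ, v_BG) | N(μ, v_BG) | v_FG / v_BG |

Defaults: v = 1 (VM) and μ = 0 (VV). All `v` parameters are **variances**.
Under VV the control-FG cell shares the BG distribution: only diseased
samples express the planted module abnormally. Note the FG × case cell of VV
uses v_FG — a variance-varying model in which every cell used v_BG would
carry no signal at all, contradicting the v_FG/v_BG signal-strength
definition, so the package implements the only self-consistent reading.

Default sweep grids (overridable in the run config): VM signal strengths
{0, 0.25, 0.5, 1, 1.5, 2}; VV variance ratios {1, 2, 4, 8}. The VM grid
spans "invisible" to roughly two noise standard deviations of separation;
the VV grid spans ratio 1 (null) to 8, beyond which variance tests saturate.

The matrix is produced by a single vectorised draw against per-entry
mean/scale arrays from `numpy.random.default_rng(seed)`, so identical inputs
give bitwise-identical output.

**What the simulation does not model:** gene–gene correlation, batch
effects, missing values, count (RNA-seq) noise, or any dependence of
expression on network degree. Passing benchmarks here therefore show that a
method can exploit planted location/scale signal on a topology — not that it
handles the full covariance structure of real expression data.

## Tool-input preprocessing

`differential_stats` reduces a dataset to one row per gene: Welch
(unequal-variance) t statistic, two-sided p-value, Benjamini–Hochberg
adjusted p-value, and the class means. Welch is the single documented
default because the VV model deliberately breaks variance homogeneity;
adapters may use either the raw or adjusted p-values. Degenerate genes
(zero variance in both classes) get p = 1 when the class means are equal
and p = 0 otherwise.

## Sparsity metrics

For an FG set *F*:

* **Global FG proximity** — edge count of an approximate minimum Steiner
  tree covering *F*: the smallest connected structure touching every FG
  gene. "Smallest covering structure" is formalised as a tree; the
  metric-closure 2-approximation (Kou: MST of the pairwise-distance complete
  graph on *F*, expanded back into shortest paths) keeps it polynomial.
  Property tests check the 2× bound against exhaustive enumeration on small
  graphs; for |F| ≤ 3 the approximation matched the exact optimum on every
  fixture tested.
* **Global FG connectivity** — mean degree of FG nodes *in the full
  network* (not the induced subgraph).
* **Local FG density** — |E(G[F])| / C(|F|, 2); undefined (an error) for
  |F| < 2 so degenerate configurations surface early rather than scoring 0.

Raising the AVD_k target k lowers the expected local density and raises the
covering-tree size — the "sparsity" dial seen from three angles.

## Evaluation protocol

Node-level binary classification with FG as the positive class:
precision = tp/(tp+fp) (0 when nothing is predicted), recall = tp/(tp+fn),
and the F-measure is F1, their harmonic mean (0 when both are 0). Predicted
edges are ignored and BG nodes get no partial credit for proximity to FG.
When a tool reports several modules, the union of their nodes is evaluated
as one prediction.

The benchmark runner sweeps the full Cartesian product
splits × simulation configs × adapters × internal-parameter values. The
expression seed for split *i* is `config.seed + 10007·i`, so each cell is
independently reproducible. Adapter failures become `status="failed"` rows
rather than aborting the sweep; with an output directory the sweep writes a
manifest keyed on a hash of its definition and skips already-recorded runs
on resume.

Two built-in baselines bracket the interesting regime: `top_n_differential`
(the n smallest p-values, topology-blind; its expected F at signal 0 is
the hypergeometric random-overlap floor E[TP]/n) and `greedy_module`
(p-value-greedy connected growth from the most significant gene; a minimal
aggregate-score method). External tools plug in as subprocesses via a
command template receiving network/expression/stats/params file paths and
writing one node ID per line.

## Numerical and design conventions

* Distances are unweighted hop counts; the framework has no edge weights.
* All randomness flows from explicit integer seeds; no global RNG state.
  Greedy tie-breaks draw from the call's own `random.Random(seed)`.
* Network inputs are deduplicated (including reversed duplicates) and
  self-loops dropped, with counts logged. Restriction to the largest
  connected component is an explicit, logged configuration step
  (`restrict_to_lcc`, default on) rather than a silent default, since
  shortest-path-based selection is only well-defined within a component;
  equal-sized component ties break toward the lexicographically smallest
  member node.
* The synthetic-network generator's preferential-attachment default is
  m = 2 (mean degree ≈ 4 at 500 nodes): sparse, connected, scale-free —
  the same qualitative regime as curated protein-interaction networks,
  at a size where a full sweep runs in seconds.
* Aggregation reports population (ddof = 0) standard deviations so a
  single-run group reports 0 rather than NaN.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run on a 500-node
preferential-attachment network with FG sets of 20 nodes, 30 FG sets per
condition for the monotonicity checks, 20 heuristic runs for the AVD_3
distance band, 50 simulations for the null-calibration floor, and ~100
random graphs with |V| ≤ 14 for oracle-equivalence checks. These sizes give
stable Monte-Carlo means while keeping a full run under a minute; the
library itself handles networks of HPRD/I2D scale (10⁴–10⁵ edges), where
AVD_k generation remains near-linear per step.

## Known limitations

* The greedy AVD_k heuristic is not complete: on adversarial graphs it can
  miss feasible sets even with many restarts (the oracle-equivalence
  property is verified empirically on random graphs, not proven).
* Global FG proximity is a 2-approximation; reported values can exceed the
  true minimum covering tree by up to a factor of two.
* Simulated expression is Gaussian and independent across genes (see above);
  rankings of real tools on real data may differ.
* The evaluation is purely node-based; methods that recover correct topology
  but pad their modules with BG nodes are penalised identically to methods
  that scatter predictions.
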