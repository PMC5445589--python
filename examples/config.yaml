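# Example pathbench run configuration (schema version 1).
# All randomness flows from the single master seed.
schema_version: 1
seed: 42

network:
  # either a file...
  #   path: hprd_edges.tsv
  #   format: tsv            # or sif
  # ...or a synthetic stand-in:
  synthetic:
    model: preferential_attachment   # or ring_lattice, erdos_renyi
    n_nodes: 500
    params: {m: 2}
  restrict_to_lcc: true

fg_selection:
  generator: AVDk            # or SAE
  n: 20                      # target FG size
  k: 3                       # target average pairwise distance (AVDk)
  alpha: 1                   # tolerance around k
  count: 80                  # number of gold-standard splits
  max_restarts: 50

simulation:
  model: VM                  # or VV
  n_cases: 100
  n_controls: 10
  # omit to use the model's default grid
  # (VM: [0, 0.25, 0.5, 1, 1.5, 2]; VV: [1, 2, 4, 8])
  signal_strengths: [0, 0.5, 1, 2]

adapters:
  - name: greedy_module
    builtin: greedy_module
    ip_grid:
      n: [10, 20, 40]        # internal-parameter grid: Cartesian over keys
  - name: top_n
    builtin: top_n_differential
    ip_grid:
      n: [20]
  # external tools plug in via a command template; placeholders:
  # {network} {expression} {labels} {stats} {params} {out}
  # - name: my_tool
  #   command: "my_tool --net {network} --pvals {stats} --conf {params} --out {out}"
  #   timeout: 600
  #   ip_grid: {fdr: [0.01, 0.05, 0.1]}
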