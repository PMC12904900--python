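# Full-pipeline configuration for `powerneurons run --config ...`.
# Omitting arcs_path/nodes_path makes the pipeline generate a synthetic
# connectome from the `synthetic` block instead of loading files.
synthetic:
  n_per_hemisphere: 300
q: 0.20
min_count: 4
qap_permutations: 500
alpha: 0.05
rich_club_threshold: 37
homolog_strategy: explicit_column
scan_thresholds: [1, 2, 3, 4, 5, 6, 8, 10]
conventions:
  closeness_direction: out
  eigenvector_direction: in
  path_metric_scope: largest_scc
  betweenness_backend: auto
seed: 11
out_dir: run
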