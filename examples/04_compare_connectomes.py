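"""Compare centrality distributions between two connectomes.

Emulates a developmental comparison: a small dense network against a
larger sparser one. Centralities are normalized by their maximum possible
values, log10(1+x)-transformed, and compared with KS and Mann-Whitney U
tests (BH-adjusted), Cliff's delta, medians, a pooled 95th-percentile
composition, and a subsampling control for the size imbalance.
"""

import numpy as np

from powerneurons import (
    SyntheticConfig,
    compare_centrality_tables,
    compute_centralities,
    generate_connectome,
    log_transform,
    normalize_centrality,
    percentile_composition,
    subsample_ks,
)

dense, _ = generate_connectome(SyntheticConfig(n_per_hemisphere=250, seed=1))
sparse_config = SyntheticConfig(
    n_per_hemisphere=600,
    base_block_prob=None,  # default blocks, thinned below via propensities
    degree_propensity=(-1.2, 1.0),  # lower median propensity -> sparser graph
    seed=2,
)
sparse, _ = generate_connectome(sparse_config)
print(f"network A: {dense.n_nodes} nodes, {dense.n_arcs} arcs "
      f"(density {dense.n_arcs / (dense.n_nodes * (dense.n_nodes - 1)):.4f})")
print(f"network B: {sparse.n_nodes} nodes, {sparse.n_arcs} arcs "
      f"(density {sparse.n_arcs / (sparse.n_nodes * (sparse.n_nodes - 1)):.4f})")

table_a = compute_centralities(dense)
table_b = compute_centralities(sparse)

print("\ncentrality distribution comparison (A vs B, normalized, log scale):")
print(f"{'centrality':12s} {'KS D':>6s} {'MWU p (BH)':>11s} {'delta':>6s} "
      f"{'median A':>9s} {'median B':>9s}")
for r in compare_centrality_tables(table_a, table_b):
    print(f"{r.centrality_name:12s} {r.ks_D:6.3f} {r.mwu_p_adjusted:11.2e} "
          f"{r.cliffs_delta:6.2f} {r.median_a:9.4f} {r.median_b:9.4f}")
print("delta near +1: A's values dominate B's pairwise; near 0: no shift")

norm_a = log_transform(normalize_centrality(table_a["degree"], "degree", len(table_a)))
norm_b = log_transform(normalize_centrality(table_b["degree"], "degree", len(table_b)))
frac_a, frac_b = percentile_composition(norm_a, norm_b, percentile=95)
print(f"\npooled 95th-percentile composition (normalized degree): "
      f"{frac_a:.1%} of A exceeds the cutoff vs {frac_b:.1%} of B")

report = subsample_ks(
    table_b["degree"].to_numpy(dtype=float),
    table_a["degree"].to_numpy(dtype=float),
    n_sub=len(table_a),
    reps=200,
    p_threshold=0.001,
    seed=3,
)
print(f"\nsubsampling control ({report.reps}x draws of {report.n_sub} from B): "
      f"KS D = {report.ks_D_mean:.4f} +/- {report.ks_D_std:.4f}, "
      f"{report.frac_p_below:.0%} of draws below p = {report.threshold}")
print("a stable, large D under equal sample sizes shows the degree "
      "difference is not an artifact of B being bigger")
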