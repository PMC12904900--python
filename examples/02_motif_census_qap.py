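"""Census the connectome motifs anchored on power neurons and test them.

A motif collapses a core neuron's in/out neighborhoods onto neuronal
groups. The census counts how many power neurons share each signature;
the QAP test permutes group labels (structure fixed) to ask whether a
signature recurs more often than labels alone would explain.
"""

from powerneurons import (
    SyntheticConfig,
    compute_centralities,
    detect_power_neurons,
    filter_frequent,
    generate_connectome,
    motif_census,
    qap_test,
    sensitivity_scan,
)

connectome, _ = generate_connectome(SyntheticConfig(n_per_hemisphere=300, seed=7))
table = compute_centralities(connectome)
_, result = detect_power_neurons(table, q=0.20)
print(f"{len(result.power_ids)} power neurons serve as motif cores")

census = motif_census(connectome, result.power_ids)
print(f"census: {len(census)} distinct motif signatures")
for stats in census[:5]:
    m = stats.motif
    print(f"  core={m.core_group!r:20s} in={sorted(m.in_groups)} "
          f"out={sorted(m.out_groups)}  count={stats.count}")

qap = qap_test(connectome, result.power_ids, census, n_permutations=500, seed=1)
frequent = filter_frequent(census, qap, min_count=4, alpha=0.05)
print(f"\nsignificant (p < 0.05) and frequent (count >= 4): {len(frequent)} motifs")
for stats in frequent[:5]:
    p = next(r.p_value for r in qap if r.motif == stats.motif)
    print(f"  count={stats.count:3d} p={p:.3f} core={stats.motif.core_group!r}")
    for g, mean in sorted(stats.mean_in_connections.items()):
        print(f"    mean in-connections from {g!r}: {mean:.2f}")

scan = sensitivity_scan(census, qap, thresholds=list(range(1, 11)), alpha=0.05)
print("\nfrequency-threshold sensitivity (retained motifs per threshold):")
print(scan.to_string(index=False))
print("the retained count is non-increasing; the knee marks where "
      "one-off signatures give way to robust, recurring motifs")
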