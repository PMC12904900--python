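"""Top-quantile sets, power-neuron detection, rich club, and backbone."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_power_ids, make_connectome, random_digraph
from powerneurons.metrics import compute_centralities
from powerneurons.model import ValidationError
from powerneurons.power import (
    backbone_report,
    backbone_subnetwork,
    degree_comparison_table,
    detect_power_neurons,
    pairwise_overlap,
    power_fraction,
    rich_club_set,
    top_quantile_set,
)


def random_centrality_table(n: int, seed: int, tie_prob: float = 0.3) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    index = [f"n{i:03d}" for i in range(n)]
    data = {}
    for col in ("degree", "closeness", "betweenness", "eigenvector"):
        values = rng.integers(0, 8, n).astype(float)  # coarse: plenty of ties
        if rng.random() > tie_prob:
            values += rng.random(n)
        data[col] = values
    frame = pd.DataFrame(data, index=index)
    frame["in_degree"] = frame["degree"] // 2
    frame["out_degree"] = frame["degree"] - frame["in_degree"]
    return frame


class TestTopQuantileSet:
    def test_distinct_values(self):
        values = {f"n{i}": float(i) for i in range(10)}
        assert top_quantile_set(values, 0.2) == {"n9", "n8"}

    def test_k_is_floor_of_qn(self):
        values = {f"n{i}": float(i) for i in range(2952)}
        assert len(top_quantile_set(values, 0.2)) == 590

    def test_ties_broken_by_ascending_id(self):
        values = {c: 1.0 for c in "edcba"}
        assert top_quantile_set(values, 0.4) == {"a", "b"}

    def test_boundary_ties_option_admits_all_tied(self):
        values = {"a": 2.0, "b": 1.0, "c": 1.0, "d": 0.0}
        assert top_quantile_set(values, 0.5, include_boundary_ties=True) == {
            "a",
            "b",
            "c",
        }

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 2.0])
    def test_q_outside_unit_interval_rejected(self, q):
        with pytest.raises(ValidationError):
            top_quantile_set({"a": 1.0, "b": 2.0}, q)


class TestDetectPowerNeurons:
    def test_identical_rankings_give_full_overlap(self):
        table = pd.DataFrame(
            {c: np.arange(10.0) for c in ("degree", "closeness", "betweenness", "eigenvector")},
            index=[f"n{i}" for i in range(10)],
        )
        top, result = detect_power_neurons(table, 0.2)
        assert result.power_ids == top["degree"]
        assert result.four_way_overlap_pct == 100.0

    def test_disjoint_top_sets_give_empty_power_set(self):
        index = [f"n{i}" for i in range(8)]
        table = pd.DataFrame(index=index)
        # each centrality ranks a different pair on top
        for j, col in enumerate(("degree", "closeness", "betweenness", "eigenvector")):
            values = np.zeros(8)
            values[2 * j : 2 * j + 2] = [2.0, 1.0]
            table[col] = values
        _, result = detect_power_neurons(table, 0.25)
        assert result.power_ids == set()
        assert result.four_way_overlap_pct == 0.0

    def test_power_fraction_product(self):
        assert power_fraction(27.46, 0.20) == pytest.approx(0.05492)

    def test_fraction_consistent_with_overlap(self):
        table = random_centrality_table(50, seed=3)
        _, result = detect_power_neurons(table, 0.2)
        assert result.power_fraction == pytest.approx(
            power_fraction(result.four_way_overlap_pct, 0.2), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_sort_and_intersect(self, seed):
        table = random_centrality_table(30, seed=seed)
        _, result = detect_power_neurons(table, 0.2)
        assert result.power_ids == brute_force_power_ids(table, 0.2)

    @pytest.mark.parametrize("seed", range(4))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        table = random_centrality_table(40, seed=seed)
        _, base = detect_power_neurons(table, 0.2)
        transformed = table.copy()
        transformed["degree"] = np.exp(table["degree"])
        transformed["closeness"] = 3 * table["closeness"] + 7
        transformed["betweenness"] = np.log1p(table["betweenness"])
        transformed["eigenvector"] = table["eigenvector"] ** 3
        _, after = detect_power_neurons(transformed, 0.2)
        assert after.power_ids == base.power_ids

    def test_power_set_contained_in_every_top_set(self, small_synthetic):
        connectome, _ = small_synthetic
        top, result = detect_power_neurons(compute_centralities(connectome), 0.2)
        for name in top.sets:
            assert result.power_ids <= top.sets[name]
        assert len(result.power_ids) <= top.k

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError, match="lacks"):
            detect_power_neurons(pd.DataFrame({"degree": [1.0]}), 0.2)


class TestPairwiseOverlap:
    def test_identical_and_half_overlapping_sets(self):
        from powerneurons.power import TopSets

        full = {"a", "b", "c", "d"}
        half = {"a", "b", "x", "y"}
        top = TopSets(q=0.5, k=4, sets={"p": full, "q": set(full), "r": half})
        overlaps = pairwise_overlap(top)
        assert overlaps[("p", "q")] == 100.0
        assert overlaps[("p", "r")] == 50.0


class TestRichClub:
    def test_threshold_is_strict(self):
        arcs = [("hub", f"n{i}") for i in range(38)]
        connectome = make_connectome(arcs)
        assert rich_club_set(connectome, 37) == {"hub"}
        assert rich_club_set(connectome, 38) == set()

    def test_zero_threshold_selects_non_isolated(self):
        connectome = make_connectome([("a", "b")], nodes={"iso": {}})
        assert rich_club_set(connectome, 0) == {"a", "b"}


class TestBackbone:
    def test_induced_subgraph_keeps_internal_arcs_only(self):
        connectome = make_connectome([("a", "b"), ("b", "c")])
        sub = backbone_subnetwork(connectome, {"a", "b"})
        assert set(sub.arcs()) == {("a", "b")}

    def test_full_id_set_is_identity(self, small_synthetic):
        connectome, _ = small_synthetic
        assert backbone_subnetwork(connectome, connectome.node_ids()) == connectome

    def test_unknown_id_rejected(self):
        with pytest.raises(ValidationError):
            backbone_subnetwork(make_connectome([("a", "b")]), {"zzz"})

    def test_report_ratios_are_one_for_full_graph(self, small_synthetic):
        connectome, _ = small_synthetic
        report = backbone_report(connectome, connectome.node_ids())
        assert report.ratios["density"] == pytest.approx(1.0)
        assert report.ratios["normalized_avg_degree"] == pytest.approx(1.0)

    def test_planted_backbone_is_denser(self, small_synthetic):
        connectome, truth = small_synthetic
        report = backbone_report(connectome, truth.planted_hub_ids)
        assert report.ratios["density"] > 1.0

    def test_mean_degree_times_count_equals_degree_sum(self, small_synthetic):
        connectome, _ = small_synthetic
        table = compute_centralities(connectome)
        _, result = detect_power_neurons(table, 0.2)
        comparison = degree_comparison_table(table, result.power_ids)
        power_row = comparison[comparison["population"] == "power neurons"].iloc[0]
        total = power_row["degree_mean"] * power_row["n"]
        assert total == pytest.approx(
            table.loc[sorted(result.power_ids), "degree"].sum()
        )
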