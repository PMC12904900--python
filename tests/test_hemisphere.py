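"""Homolog pairing, hemisphere tables, and intergroup graphs."""

import pytest

from conftest import make_connectome
from powerneurons.hemisphere import (
    group_side_distribution,
    hemisphere_table,
    infer_homologs,
    intergroup_graph,
)
from powerneurons.metrics import compute_centralities
from powerneurons.model import ValidationError
from powerneurons.power import PowerResult, detect_power_neurons
from powerneurons.synthetic import SyntheticConfig, generate_connectome


def power_result(ids: set[str], n: int = 10) -> PowerResult:
    return PowerResult(
        power_ids=ids,
        pairwise_overlap_pct={},
        four_way_overlap_pct=0.0,
        power_fraction=len(ids) / n,
        q=0.2,
        n=n,
    )


class TestInferHomologs:
    def test_explicit_mutual_pair(self):
        nodes = {
            "l1": {"side": "left", "homolog_id": "r1"},
            "r1": {"side": "right", "homolog_id": "l1"},
        }
        pairing = infer_homologs(make_connectome([], nodes), "explicit_column")
        assert pairing.pairs == [("l1", "r1")]

    def test_explicit_same_side_rejected(self):
        nodes = {
            "l1": {"side": "left", "homolog_id": "l2"},
            "l2": {"side": "left", "homolog_id": "l1"},
        }
        with pytest.raises(ValidationError, match="left/right"):
            infer_homologs(make_connectome([], nodes), "explicit_column")

    def test_explicit_non_mutual_rejected(self):
        nodes = {
            "l1": {"side": "left", "homolog_id": "r1"},
            "r1": {"side": "right", "homolog_id": None},
        }
        with pytest.raises(ValidationError, match="mutual"):
            infer_homologs(make_connectome([], nodes), "explicit_column")

    def test_attribute_match_pairs_identical_tuples(self):
        nodes = {
            "l1": {"side": "left", "group": "G", "extra": {"ct": "KC1"}},
            "r1": {"side": "right", "group": "G", "extra": {"ct": "KC1"}},
            "l2": {"side": "left", "group": "G", "extra": {"ct": "unique"}},
        }
        pairing = infer_homologs(make_connectome([], nodes), "attribute_match")
        assert pairing.pairs == [("l1", "r1")]
        assert "l2" in pairing.unpaired
        assert pairing.ambiguous == []

    def test_attribute_match_greedy_on_ambiguous_class(self):
        nodes = {
            f"{s}{i}": {"side": side, "group": "G", "extra": {"ct": "X"}}
            for s, side in (("l", "left"), ("r", "right"))
            for i in (1, 2)
        }
        pairing = infer_homologs(make_connectome([], nodes), "attribute_match")
        assert pairing.pairs == [("l1", "r1"), ("l2", "r2")]
        assert len(pairing.ambiguous) == 1

    def test_attribute_match_requires_extra_columns(self):
        nodes = {"a": {"side": "left", "group": "G"}}
        with pytest.raises(ValidationError, match="extra attribute"):
            infer_homologs(make_connectome([], nodes), "attribute_match")

    def test_recovers_all_pairs_on_noise_free_mirror(self):
        connectome, truth = generate_connectome(
            SyntheticConfig(n_per_hemisphere=100, mirror_noise=0.0, seed=9)
        )
        pairing = infer_homologs(connectome, "attribute_match")
        assert set(pairing.pairs) == set(truth.homolog_pairs)


class TestHemisphereTable:
    def test_row_identities_on_synthetic(self, small_synthetic):
        connectome, _ = small_synthetic
        _, result = detect_power_neurons(compute_centralities(connectome), 0.2)
        pairing = infer_homologs(connectome, "explicit_column")
        table, excluded = hemisphere_table(result, pairing, connectome)
        for side in ("left", "right"):
            col = table[side]
            assert (
                col["power neurons without a homolog"]
                + col["power neurons with a homolog"]
                == col["power neurons"]
            )
            assert (
                col["power neurons whose homolog is a power neuron"]
                + col["power neurons whose homolog is not a power neuron"]
                == col["power neurons with a homolog"]
            )
        assert excluded + table.loc["power neurons"].sum() == len(result.power_ids)

    def test_unknown_side_power_neuron_excluded(self):
        nodes = {
            "l1": {"side": "left"},
            "u1": {"side": "unknown"},
        }
        connectome = make_connectome([], nodes)
        pairing = infer_homologs(connectome, "explicit_column")
        table, excluded = hemisphere_table(
            power_result({"l1", "u1"}), pairing, connectome
        )
        assert excluded == 1
        assert table.loc["power neurons", "left"] == 1

    def test_all_mutual_power_pairs_zero_not_power_row(self):
        nodes = {
            "l1": {"side": "left", "homolog_id": "r1"},
            "r1": {"side": "right", "homolog_id": "l1"},
        }
        connectome = make_connectome([], nodes)
        pairing = infer_homologs(connectome, "explicit_column")
        table, _ = hemisphere_table(power_result({"l1", "r1"}), pairing, connectome)
        assert (
            table.loc["power neurons whose homolog is not a power neuron"].sum() == 0
        )


class TestGroupSideDistribution:
    def test_percentages_use_group_side_denominator(self):
        nodes = {
            **{f"g{i}": {"group": "G", "side": "left"} for i in range(10)},
            "u": {"group": None, "side": "left"},
        }
        connectome = make_connectome([], nodes)
        frame = group_side_distribution(
            power_result({"g0", "g1", "g2", "u"}), connectome
        )
        g_row = frame[(frame["group"] == "G") & (frame["side"] == "left")].iloc[0]
        assert g_row["power_pct"] == pytest.approx(30.0)
        unclassified = frame[frame["group"] == "unclassified"].iloc[0]
        assert unclassified["n_power"] == 1
        assert unclassified["power_pct"] != unclassified["power_pct"]  # NaN

    def test_group_with_no_power_neurons(self):
        nodes = {"a": {"group": "G", "side": "left"}}
        frame = group_side_distribution(power_result(set()), make_connectome([], nodes))
        assert frame.iloc[0]["power_pct"] == 0.0


class TestIntergroupGraph:
    def test_hand_counted_edge_weight(self, labeled_toy):
        result = intergroup_graph(labeled_toy, {"a1"}, "at_least_one")
        assert result.graph[("G", "left")][("H", "right")]["weight"] == 3
        assert result.graph.nodes[("G", "left")]["n_power"] == 1

    def test_no_power_neurons_yields_empty_edges(self, labeled_toy):
        result = intergroup_graph(labeled_toy, set(), "at_least_one")
        assert result.graph.number_of_edges() == 0

    def test_both_mode_is_pointwise_dominated(self, small_synthetic):
        connectome, _ = small_synthetic
        _, power = detect_power_neurons(compute_centralities(connectome), 0.2)
        loose = intergroup_graph(connectome, power.power_ids, "at_least_one")
        strict = intergroup_graph(connectome, power.power_ids, "both")
        for u, v, w in strict.graph.edges(data="weight"):
            assert loose.graph.has_edge(u, v)
            assert w <= loose.graph[u][v]["weight"]

    def test_arc_conservation(self, small_synthetic):
        connectome, _ = small_synthetic
        _, power = detect_power_neurons(compute_centralities(connectome), 0.2)
        result = intergroup_graph(connectome, power.power_ids, "at_least_one")
        assert (
            result.total_edge_weight()
            + result.skipped_arcs
            + result.non_qualifying_arcs
            == connectome.n_arcs
        )

    def test_unknown_mode_rejected(self, labeled_toy):
        with pytest.raises(ValidationError):
            intergroup_graph(labeled_toy, set(), "either")

    def test_undirected_aggregate_sums_directions(self):
        nodes = {
            "p": {"group": "G", "side": "left"},
            "q": {"group": "H", "side": "right"},
        }
        connectome = make_connectome([("p", "q"), ("q", "p")], nodes)
        result = intergroup_graph(connectome, {"p", "q"}, "both")
        und = result.to_undirected()
        assert und[("G", "left")][("H", "right")]["weight"] == 2
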