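"""Motif construction, census, QAP test, and frequency filtering."""

import numpy as np
import pytest

from conftest import brute_force_motif_census, make_connectome
from powerneurons.model import ValidationError
from powerneurons.motifs import (
    ConnectomeMotif,
    MotifStats,
    QAPResult,
    build_motif,
    filter_frequent,
    motif_census,
    qap_p_value,
    qap_test,
    sensitivity_scan,
)


@pytest.fixture
def grouped_graph():
    nodes = {
        "core": {"group": "A"},
        "inA": {"group": "A"},
        "inB1": {"group": "B"},
        "inB2": {"group": "B"},
        "outC": {"group": "C"},
        "null": {"group": None},
    }
    arcs = [
        ("inA", "core"),
        ("inB1", "core"),
        ("inB2", "core"),
        ("core", "outC"),
        ("null", "core"),
    ]
    return make_connectome(arcs, nodes)


class TestBuildMotif:
    def test_neighborhood_groups_and_counts(self, grouped_graph):
        obs = build_motif(grouped_graph, "core")
        assert obs.motif == ConnectomeMotif("A", frozenset("AB"), frozenset("C"))
        assert obs.in_counts == {"A": 1, "B": 2}
        assert obs.out_counts == {"C": 1}
        assert obs.null_in_neighbors == 1

    def test_isolated_core_has_empty_sets(self):
        connectome = make_connectome([], {"solo": {"group": "A"}})
        obs = build_motif(connectome, "solo")
        assert obs.motif == ConnectomeMotif("A", frozenset(), frozenset())

    def test_null_group_core_yields_none(self, grouped_graph):
        assert build_motif(grouped_graph, "null").motif is None

    def test_unknown_core_rejected(self, grouped_graph):
        with pytest.raises(ValidationError):
            build_motif(grouped_graph, "ghost")


class TestMotifCensus:
    def test_mean_connection_counts_average_occurrences(self):
        nodes = {
            "c1": {"group": "A"},
            "c2": {"group": "A"},
            **{f"b{i}": {"group": "B"} for i in range(6)},
        }
        arcs = [("b0", "c1"), ("b1", "c1")]  # c1: 2 in-neighbors in B
        arcs += [(f"b{i}", "c2") for i in range(2, 6)]  # c2: 4
        census = motif_census(make_connectome(arcs, nodes), {"c1", "c2"})
        (stats,) = census
        assert stats.count == 2
        assert stats.mean_in_connections["B"] == pytest.approx(3.0)

    def test_distinct_keys_counted_separately(self, grouped_graph):
        census = motif_census(grouped_graph, {"core", "inA"})
        assert sorted(s.count for s in census) == [1, 1]

    def test_empty_core_set(self, grouped_graph):
        assert motif_census(grouped_graph, set()) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_labeled_graphs(self, seed):
        rng = np.random.default_rng(seed)
        groups = ["A", "B", "C", None]
        nodes = {
            f"n{i}": {"group": groups[rng.integers(len(groups))]} for i in range(12)
        }
        arcs = list(
            {
                (f"n{rng.integers(12)}", f"n{rng.integers(12)}")
                for _ in range(45)
            }
        )
        arcs = [(u, v) for u, v in arcs if u != v]
        connectome = make_connectome(arcs, nodes)
        cores = set(nodes)
        census = motif_census(connectome, cores)
        oracle = brute_force_motif_census(connectome, cores)
        ours = {
            (s.motif.core_group, s.motif.in_groups, s.motif.out_groups): s.count
            for s in census
        }
        assert ours == oracle

    def test_census_deterministic_under_iteration_order(self, grouped_graph):
        a = motif_census(grouped_graph, {"core", "inA", "inB1"})
        b = motif_census(grouped_graph, {"inB1", "core", "inA"})
        assert [(s.motif, s.count) for s in a] == [(s.motif, s.count) for s in b]


class TestQAP:
    def test_p_value_hand_example(self):
        assert qap_p_value(5, [7, 3, 5, 9]) == 0.5

    def test_p_zero_when_observed_dominates(self):
        assert qap_p_value(9, [7, 3, 5, 9]) == 0.0

    def test_p_one_when_all_exceed(self):
        assert qap_p_value(0, [1, 2, 3]) == 1.0

    def test_degenerate_single_group_gives_p_zero(self):
        nodes = {f"n{i}": {"group": "only"} for i in range(6)}
        arcs = [(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)]
        connectome = make_connectome(arcs, nodes)
        cores = set(nodes)
        census = motif_census(connectome, cores)
        results = qap_test(connectome, cores, census, n_permutations=50, seed=0)
        for r in results:
            assert r.null_counts == [r.gamma_obs] * 50
            assert r.p_value == 0.0

    def test_deterministic_given_seed(self, small_synthetic):
        connectome, truth = small_synthetic
        cores = set(list(truth.planted_hub_ids)[:20])
        census = motif_census(connectome, cores)
        a = qap_test(connectome, cores, census, n_permutations=30, seed=5)
        b = qap_test(connectome, cores, census, n_permutations=30, seed=5)
        assert [(r.motif, r.null_counts) for r in a] == [
            (r.motif, r.null_counts) for r in b
        ]

    def test_invalid_permutation_count(self, grouped_graph):
        census = motif_census(grouped_graph, {"core"})
        with pytest.raises(ValidationError):
            qap_test(grouped_graph, {"core"}, census, n_permutations=0)

    def test_label_permutation_maps_census_keys(self, small_synthetic):
        """Relabeling groups by a bijection permutes keys but not counts."""
        connectome, truth = small_synthetic
        cores = set(list(truth.planted_hub_ids)[:20])
        before = motif_census(connectome, cores)
        groups = sorted(connectome.groups())
        mapping = dict(zip(groups, groups[1:] + groups[:1]))
        relabeled = connectome.copy()
        for rec in relabeled.records():
            if rec.group is not None:
                rec.group = mapping[rec.group]
        after = motif_census(relabeled, cores)

        def mapped(motif):
            return ConnectomeMotif(
                mapping[motif.core_group],
                frozenset(mapping[g] for g in motif.in_groups),
                frozenset(mapping[g] for g in motif.out_groups),
            )

        assert {(mapped(s.motif), s.count) for s in before} == {
            (s.motif, s.count) for s in after
        }


def fake_census(counts: dict[str, int]) -> list[MotifStats]:
    return [
        MotifStats(
            motif=ConnectomeMotif(name, frozenset({"X"}), frozenset({"Y"})),
            count=c,
            core_ids={f"{name}{i}" for i in range(c)},
            mean_in_connections={"X": 1.0},
            mean_out_connections={"Y": 1.0},
        )
        for name, c in counts.items()
    ]


def fake_qap(census: list[MotifStats], p: float = 0.0) -> list[QAPResult]:
    return [
        QAPResult(s.motif, s.count, [0], 1, p_value=p) for s in census
    ]


class TestFilterAndScan:
    def test_frequency_threshold_retains_frequent_significant(self):
        census = fake_census({"a": 26, "b": 13, "c": 3})
        kept = filter_frequent(census, fake_qap(census), min_count=4)
        assert [s.count for s in kept] == [26, 13]

    def test_alpha_zero_removes_everything(self):
        census = fake_census({"a": 26})
        assert filter_frequent(census, fake_qap(census), 1, alpha=0.0) == []

    def test_all_significant_min_one_keeps_all(self):
        census = fake_census({"a": 2, "b": 1})
        assert len(filter_frequent(census, fake_qap(census), 1)) == 2

    def test_mismatched_key_sets_rejected(self):
        census = fake_census({"a": 2})
        with pytest.raises(ValidationError):
            filter_frequent(census, fake_qap(fake_census({"b": 2})), 1)

    def test_scan_hand_example(self):
        census = fake_census({"a": 3, "b": 3, "c": 1})
        table = sensitivity_scan(census, fake_qap(census), [1, 2, 3])
        assert table["n_retained"].tolist() == [3, 2, 2]

    def test_scan_is_monotone_non_increasing(self):
        census = fake_census({"a": 9, "b": 5, "c": 5, "d": 2, "e": 1})
        table = sensitivity_scan(census, fake_qap(census), list(range(1, 12)))
        retained = table["n_retained"].tolist()
        assert retained == sorted(retained, reverse=True)
        assert retained[-1] == 0  # threshold above max count

    def test_scan_requires_ascending_thresholds(self):
        census = fake_census({"a": 1})
        with pytest.raises(ValidationError):
            sensitivity_scan(census, fake_qap(census), [3, 1])
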