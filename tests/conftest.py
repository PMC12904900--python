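"""Shared builders, oracles, and fixtures for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from powerneurons.model import Connectome, NodeRecord


def make_connectome(
    arcs: list[tuple[str, str]],
    nodes: dict[str, dict] | None = None,
    stage: str = "test",
) -> Connectome:
    """Hand-build a connectome; nodes default to group-null, side-unknown."""
    node_ids = set(itertools.chain.from_iterable(arcs))
    specs = dict(nodes or {})
    node_ids |= set(specs)
    connectome = Connectome(stage)
    for node_id in sorted(node_ids):
        connectome.add_node(NodeRecord(id=node_id, **specs.get(node_id, {})))
    for u, v in arcs:
        if not connectome.graph.has_edge(u, v):
            connectome.add_arc(u, v)
    return connectome


def random_digraph(n: int, p: float, seed: int) -> Connectome:
    rng = np.random.default_rng(seed)
    arcs = [
        (f"n{i}", f"n{j}")
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    nodes = {f"n{i}": {} for i in range(n)}
    return make_connectome(arcs, nodes)


# -- independent oracles ----------------------------------------------------

def brute_force_betweenness(connectome: Connectome) -> dict[str, float]:
    """Betweenness by exhaustive simple-path enumeration (endpoints excluded).

    For every ordered pair (s, t) it enumerates all simple paths, keeps the
    shortest ones, and credits each interior node with the fraction of
    shortest s-t paths through it. Exponential; n <= 12 only.
    """
    graph = connectome.graph
    nodes = list(graph.nodes)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = list(nx.all_simple_paths(graph, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            scores[v] += through / len(geodesics)
    return scores


def brute_force_motif_census(
    connectome: Connectome, core_ids: set[str]
) -> dict[tuple, int]:
    """Census by direct neighborhood set construction, key -> count."""
    counts: dict[tuple, int] = {}
    for core in core_ids:
        group = connectome.record(core).group
        if group is None:
            continue
        in_groups = frozenset(
            g
            for g in (
                connectome.record(p).group
                for p in connectome.graph.predecessors(core)
            )
            if g is not None
        )
        out_groups = frozenset(
            g
            for g in (
                connectome.record(s).group
                for s in connectome.graph.successors(core)
            )
            if g is not None
        )
        key = (group, in_groups, out_groups)
        counts[key] = counts.get(key, 0) + 1
    return counts


def brute_force_power_ids(
    centralities, q: float
) -> set[str]:
    """Power set by independent sort-and-intersect on the four columns."""
    k = int(q * len(centralities))
    sets = []
    for col in ("degree", "closeness", "betweenness", "eigenvector"):
        order = sorted(
            centralities.index, key=lambda i: (-centralities.at[i, col], i)
        )
        sets.append(set(order[:k]))
    return set.intersection(*sets)


# -- exchangeable null fixture for QAP calibration -------------------------

def exchangeable_relabeled_connectome(seed: int):
    """Label-exchangeable calibration fixture; see the synthetic module."""
    from powerneurons.synthetic import exchangeable_null_connectome

    return exchangeable_null_connectome(seed)


# -- fixtures ---------------------------------------------------------------

@pytest.fixture(scope="session")
def small_synthetic():
    """One small default-structured synthetic connectome with ground truth."""
    from powerneurons.synthetic import SyntheticConfig, generate_connectome

    return generate_connectome(SyntheticConfig(n_per_hemisphere=120, seed=7))


@pytest.fixture
def labeled_toy():
    """Two-group, two-side toy graph used across hemisphere/motif tests."""
    nodes = {
        "a1": {"group": "G", "side": "left"},
        "a2": {"group": "G", "side": "left"},
        "b1": {"group": "H", "side": "right"},
        "b2": {"group": "H", "side": "right"},
        "b3": {"group": "H", "side": "right"},
        "u1": {"group": None, "side": "unknown"},
    }
    arcs = [
        ("a1", "b1"),
        ("a1", "b2"),
        ("a1", "b3"),
        ("a2", "a1"),
        ("b1", "a2"),
        ("u1", "a1"),
    ]
    return make_connectome(arcs, nodes)
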