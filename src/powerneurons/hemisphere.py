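"""Homolog pairing, hemisphere tables, and power-mediated group graphs.

Two neurons are homologous when their connection structure matches across
hemispheres. Larval-style data declares pairs explicitly; adult-style data
does not, and pairs are inferred by matching the full tuple of neuronal
attributes (group plus every extra column) between a left and a right
neuron.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .model import Connectome, ValidationError
from .power import PowerResult

INTERGROUP_MODES = ("at_least_one", "both")


@dataclass
class HomologPairing:
    pairs: list[tuple[str, str]]  # (left id, right id)
    unpaired: set[str]
    ambiguous: list[tuple[tuple, list[str]]] = field(default_factory=list)

    def partner(self) -> dict[str, str]:
        mapping = {}
        for left, right in self.pairs:
            mapping[left] = right
            mapping[right] = left
        return mapping


def infer_homologs(
    connectome: Connectome, strategy: str = "attribute_match"
) -> HomologPairing:
    """Pair left/right homologs.

    ``explicit_column`` trusts each node's declared homolog id, validating
    that declarations are mutual and cross-side. ``attribute_match`` groups
    nodes by their full attribute tuple and pairs left against right members
    within each class; classes with several candidates on both sides are
    paired greedily by ascending id and recorded as ambiguous. Nodes of
    unknown side are never paired.
    """
    if strategy == "explicit_column":
        return _pair_explicit(connectome)
    if strategy == "attribute_match":
        return _pair_by_attributes(connectome)
    raise ValidationError(f"unknown homolog strategy {strategy!r}")


def _pair_explicit(connectome: Connectome) -> HomologPairing:
    pairs, unpaired, seen = [], set(), set()
    for rec in connectome.records():
        if rec.id in seen:
            continue
        if rec.homolog_id is None:
            unpaired.add(rec.id)
            continue
        other = connectome.record(rec.homolog_id)  # raises on dangling id
        if other.homolog_id != rec.id:
            raise ValidationError(
                f"homolog declaration not mutual: {rec.id!r} -> {other.id!r}"
            )
        if {rec.side, other.side} != {"left", "right"}:
            raise ValidationError(
                f"homolog pair ({rec.id!r}, {other.id!r}) must span left/right, "
                f"got sides ({rec.side}, {other.side})"
            )
        left, right = (rec, other) if rec.side == "left" else (other, rec)
        pairs.append((left.id, right.id))
        seen.update((rec.id, other.id))
    return HomologPairing(sorted(pairs), unpaired)


def _pair_by_attributes(connectome: Connectome) -> HomologPairing:
    has_extra = any(rec.extra for rec in connectome.records())
    if not has_extra:
        raise ValidationError(
            "attribute_match needs at least one extra attribute column"
        )
    classes: dict[tuple, dict[str, list[str]]] = defaultdict(
        lambda: {"left": [], "right": []}
    )
    unpaired: set[str] = set()
    for rec in connectome.records():
        if rec.side in ("left", "right"):
            classes[rec.attribute_tuple()][rec.side].append(rec.id)
        else:
            unpaired.add(rec.id)
    pairs, ambiguous = [], []
    for key in sorted(classes, key=repr):
        left = sorted(classes[key]["left"])
        right = sorted(classes[key]["right"])
        matched = min(len(left), len(right))
        if len(left) > 1 and len(right) > 1:
            ambiguous.append((key, left + right))
        pairs.extend(zip(left[:matched], right[:matched]))
        unpaired.update(left[matched:])
        unpaired.update(right[matched:])
    return HomologPairing(sorted(pairs), unpaired, ambiguous)


HEMISPHERE_ROWS = (
    "power neurons",
    "power neurons without a homolog",
    "power neurons with a homolog",
    "power neurons whose homolog is a power neuron",
    "power neurons whose homolog is not a power neuron",
)


def hemisphere_table(
    power: PowerResult, pairing: HomologPairing, connectome: Connectome
) -> tuple[pd.DataFrame, int]:
    """Distribution of power neurons across hemispheres.

    Rows: total, without/with homolog, homolog is / is not a power neuron;
    columns: left, right. Power neurons of unknown side are excluded from
    the table and returned as a separate count. Row identities hold by
    construction: with + without = total, is-power + not-power = with.
    """
    partner = pairing.partner()
    counts = {row: {"left": 0, "right": 0} for row in HEMISPHERE_ROWS}
    excluded_unknown_side = 0
    for node_id in sorted(power.power_ids):
        side = connectome.record(node_id).side
        if side not in ("left", "right"):
            excluded_unknown_side += 1
            continue
        counts["power neurons"][side] += 1
        mate = partner.get(node_id)
        if mate is None:
            counts["power neurons without a homolog"][side] += 1
            continue
        counts["power neurons with a homolog"][side] += 1
        if mate in power.power_ids:
            counts["power neurons whose homolog is a power neuron"][side] += 1
        else:
            counts["power neurons whose homolog is not a power neuron"][side] += 1
    frame = pd.DataFrame(counts).T[["left", "right"]]
    frame.index.name = "property"
    return frame, excluded_unknown_side


UNCLASSIFIED = "unclassified"


def group_side_distribution(
    power: PowerResult, connectome: Connectome
) -> pd.DataFrame:
    """Power-neuron count and percentage per (group, side) cell.

    The percentage denominator is the number of neurons in that group/side.
    Group-null nodes are tallied under a reserved ``unclassified`` row and
    excluded from per-group percentages.
    """
    totals: dict[tuple[str, str], int] = defaultdict(int)
    power_counts: dict[tuple[str, str], int] = defaultdict(int)
    for rec in connectome.records():
        key = (rec.group if rec.group is not None else UNCLASSIFIED, rec.side)
        totals[key] += 1
        if rec.id in power.power_ids:
            power_counts[key] += 1
    rows = []
    for group, side in sorted(totals):
        n_total = totals[(group, side)]
        n_power = power_counts[(group, side)]
        rows.append(
            {
                "group": group,
                "side": side,
                "n_neurons": n_total,
                "n_power": n_power,
                "power_pct": (
                    float("nan") if group == UNCLASSIFIED else 100.0 * n_power / n_total
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IntergroupGraph:
    """Power-mediated connectivity between (group, side) blocks.

    Node weight = number of power neurons in that block; directed edge
    weight = number of neuron-to-neuron arcs between the blocks in which
    at least one endpoint (``at_least_one``) or both endpoints (``both``)
    are power neurons.
    """

    graph: nx.DiGraph
    mode: str
    skipped_arcs: int  # arcs touching null-group or unknown-side nodes
    non_qualifying_arcs: int

    def total_edge_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges(data="weight"))

    def to_undirected(self) -> nx.Graph:
        """Presentation aggregate: both directions summed per block pair."""
        und = nx.Graph()
        und.add_nodes_from(self.graph.nodes(data=True))
        for u, v, w in self.graph.edges(data="weight"):
            if und.has_edge(u, v):
                und[u][v]["weight"] += w
            else:
                und.add_edge(u, v, weight=w)
        return und


def intergroup_graph(
    connectome: Connectome, power_ids: set[str], mode: str = "at_least_one"
) -> IntergroupGraph:
    """Aggregate qualifying arcs into a (group, side)-block digraph."""
    if mode not in INTERGROUP_MODES:
        raise ValidationError(f"mode must be one of {INTERGROUP_MODES}, got {mode!r}")
    graph = nx.DiGraph()

    def block(rec) -> tuple[str, str] | None:
        if rec.group is None or rec.side not in ("left", "right"):
            return None
        return (rec.group, rec.side)

    for rec in connectome.records():
        b = block(rec)
        if b is not None and b not in graph:
            graph.add_node(b, n_power=0, group=b[0], side=b[1])
    for node_id in power_ids:
        b = block(connectome.record(node_id))
        if b is not None:
            graph.nodes[b]["n_power"] += 1

    skipped = non_qualifying = 0
    for u, v in connectome.arcs():
        bu, bv = block(connectome.record(u)), block(connectome.record(v))
        if bu is None or bv is None:
            skipped += 1
            continue
        if mode == "at_least_one":
            qualifies = u in power_ids or v in power_ids
        else:
            qualifies = u in power_ids and v in power_ids
        if not qualifies:
            non_qualifying += 1
            continue
        if graph.has_edge(bu, bv):
            graph[bu][bv]["weight"] += 1
        else:
            graph.add_edge(bu, bv, weight=1)
    return IntergroupGraph(graph, mode, skipped, non_qualifying)
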