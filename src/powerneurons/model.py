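"""Core data model: a labeled directed connectome.

A connectome is modeled as a simple directed graph C = <N, A>: one node per
neuron, one unweighted arc per ordered pair of neurons with at least one
synaptic connection. Node metadata (neuronal group, hemisphere side,
declared homolog, free-form attributes) rides along on each node and drives
every label-dependent analysis downstream (motifs, hemisphere tables,
group graphs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

SIDES = ("left", "right", "unknown")


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


class FormatError(ValidationError):
    """Raised when a file cannot be parsed under the named format."""


class ConfigurationError(ValidationError):
    """Raised for invalid configuration (unknown tokens, missing columns)."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative numerical routine fails to converge."""


def normalize_side(value: object) -> str:
    """Map free-form side strings onto {left, right, unknown}.

    Matching is case-insensitive; anything unrecognized (including missing
    values) collapses to ``unknown``.
    """
    if value is None:
        return "unknown"
    text = str(value).strip().lower()
    if text in ("left", "l"):
        return "left"
    if text in ("right", "r"):
        return "right"
    return "unknown"


@dataclass
class NodeRecord:
    """Metadata for one neuron.

    ``group`` is the neuronal group ("annotation" in larval data,
    "superclass" in adult data); ``None`` marks an unclassified neuron.
    ``extra`` holds any additional attribute columns in file order; they are
    used by attribute-based homolog inference.
    """

    id: str
    group: str | None = None
    side: str = "unknown"
    homolog_id: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("node id must be a non-empty string")
        if self.side not in SIDES:
            raise ValidationError(
                f"side must be one of {SIDES}, got {self.side!r}"
            )
        if self.homolog_id == self.id:
            raise ValidationError(f"node {self.id!r} declares itself as homolog")

    def attribute_tuple(self) -> tuple:
        """Full (group, *extra) tuple used for attribute-match pairing."""
        return (self.group, *self.extra.values())


@dataclass
class LoadReport:
    """Bookkeeping from graph construction."""

    self_loops_dropped: int = 0
    duplicate_arcs_merged: int = 0
    zero_weight_dropped: int = 0
    unknown_endpoint_arcs: int = 0
    nodes_created_lenient: int = 0

    def to_dict(self) -> dict[str, int]:
        return dict(vars(self))


class Connectome:
    """A simple directed graph over :class:`NodeRecord` nodes.

    Thin wrapper around :class:`networkx.DiGraph`; the underlying graph is
    exposed as ``.graph`` for interoperability, with node records stored
    under the ``record`` node attribute. Arcs are unweighted: existence
    means at least one connection.
    """

    def __init__(self, stage_label: str = "unnamed") -> None:
        self.stage_label = stage_label
        self.graph = nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, record: NodeRecord) -> None:
        if record.id in self.graph:
            raise ValidationError(f"duplicate node id {record.id!r}")
        self.graph.add_node(record.id, record=record)

    def add_arc(self, source: str, target: str) -> None:
        if source == target:
            raise ValidationError("self-loops are not allowed")
        for endpoint in (source, target):
            if endpoint not in self.graph:
                raise ValidationError(f"unknown endpoint {endpoint!r}")
        self.graph.add_edge(source, target)

    # -- access ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def arcs(self) -> Iterator[tuple[str, str]]:
        return iter(self.graph.edges)

    def record(self, node_id: str) -> NodeRecord:
        try:
            return self.graph.nodes[node_id]["record"]
        except KeyError:
            raise ValidationError(f"unknown node id {node_id!r}") from None

    def records(self) -> Iterator[NodeRecord]:
        for node_id in self.node_ids():
            yield self.record(node_id)

    def groups(self) -> set[str]:
        """Distinct non-null neuronal groups."""
        return {r.group for r in self.records() if r.group is not None}

    # -- derived views -----------------------------------------------------
    def induced_subgraph(self, ids: Iterable[str]) -> "Connectome":
        """Subnetwork induced by ``ids``, metadata preserved."""
        ids = set(ids)
        unknown = ids - set(self.graph.nodes)
        if unknown:
            raise ValidationError(
                f"unknown node ids in subgraph request: {sorted(unknown)[:5]}"
            )
        sub = Connectome(self.stage_label)
        for node_id in sorted(ids):
            sub.add_node(self.record(node_id))
        for u, v in self.graph.edges:
            if u in ids and v in ids:
                sub.add_arc(u, v)
        return sub

    def copy(self) -> "Connectome":
        dup = Connectome(self.stage_label)
        for rec in self.records():
            dup.add_node(
                NodeRecord(rec.id, rec.group, rec.side, rec.homolog_id, dict(rec.extra))
            )
        for u, v in self.graph.edges:
            dup.add_arc(u, v)
        return dup

    # -- export ------------------------------------------------------------
    def to_arc_triples(self) -> list[tuple[str, str, float]]:
        """Arc list as (source, target, weight=1) triples, sorted."""
        return [(u, v, 1.0) for u, v in sorted(self.graph.edges)]

    def to_node_records(self) -> list[NodeRecord]:
        return list(self.records())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        if set(self.graph.edges) != set(other.graph.edges):
            return False
        return all(
            vars(self.record(i)) == vars(other.record(i)) for i in self.graph.nodes
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Connectome(stage={self.stage_label!r}, "
            f"n_nodes={self.n_nodes}, n_arcs={self.n_arcs})"
        )


def side_counts(connectome: Connectome) -> Mapping[str, int]:
    """Number of nodes per hemisphere side."""
    counts = {s: 0 for s in SIDES}
    for rec in connectome.records():
        counts[rec.side] += 1
    return counts
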