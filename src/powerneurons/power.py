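"""Power-neuron detection, overlap tables, rich-club set, and backbone.

A power neuron simultaneously belongs to the top-quantile (default 20%)
sets of total degree, closeness, betweenness, and eigenvector centrality.
The detection is rank-based: any strictly monotone transform of a
centrality leaves the result unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .metrics import CentralityConventions, NetworkSummary, summarize
from .model import Connectome, ValidationError

POWER_CENTRALITIES = ("degree", "closeness", "betweenness", "eigenvector")


def top_quantile_set(
    values: Mapping[str, float],
    q: float,
    include_boundary_ties: bool = False,
) -> set[str]:
    """Ids of the top ``floor(q*n)`` values.

    Ranking is by value descending with ties broken by ascending id, so the
    result is deterministic. With ``include_boundary_ties`` every id tied
    with the boundary value is admitted and the set may exceed ``floor(q*n)``.
    """
    if not values:
        raise ValidationError("values must be non-empty")
    if not 0 < q < 1:
        raise ValidationError(f"q must lie in (0,1), got {q}")
    k = int(q * len(values))
    ranked = sorted(values.items(), key=lambda item: (-item[1], item[0]))
    if k == 0:
        return set()
    if include_boundary_ties:
        boundary = ranked[k - 1][1]
        return {i for i, v in ranked if v >= boundary}
    return {i for i, _ in ranked[:k]}


@dataclass
class TopSets:
    q: float
    sets: dict[str, set[str]]
    k: int

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


@dataclass
class PowerResult:
    power_ids: set[str]
    pairwise_overlap_pct: dict[tuple[str, str], float]
    four_way_overlap_pct: float
    power_fraction: float
    q: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pair": f"{a} & {b}", "overlap_pct": pct}
            for (a, b), pct in self.pairwise_overlap_pct.items()
        ]
        rows.append({"pair": "all four", "overlap_pct": self.four_way_overlap_pct})
        return pd.DataFrame(rows)


def power_fraction(four_way_overlap_pct: float, q: float) -> float:
    """Fraction of all neurons that are power neurons, (overlap/100) * q."""
    return four_way_overlap_pct / 100.0 * q


def pairwise_overlap(top_sets: TopSets) -> dict[tuple[str, str], float]:
    """Percentage overlap |A∩B|/k for each unordered pair of top sets.

    With boundary ties admitted the sets may differ in size; the denominator
    is then the smaller set's size.
    """
    overlaps = {}
    for a, b in itertools.combinations(sorted(top_sets.sets), 2):
        set_a, set_b = top_sets.sets[a], top_sets.sets[b]
        denom = min(len(set_a), len(set_b)) or 1
        overlaps[(a, b)] = 100.0 * len(set_a & set_b) / denom
    return overlaps


def detect_power_neurons(
    centralities: pd.DataFrame,
    q: float = 0.20,
    include_boundary_ties: bool = False,
) -> tuple[TopSets, PowerResult]:
    """Intersect the four per-centrality top-quantile sets.

    ``centralities`` is the table from
    :func:`powerneurons.metrics.compute_centralities`; total ``degree`` is
    the degree ranking used.
    """
    missing = [c for c in POWER_CENTRALITIES if c not in centralities.columns]
    if missing:
        raise ValidationError(f"centrality table lacks columns {missing}")
    n = len(centralities)
    sets = {
        name: top_quantile_set(
            centralities[name].to_dict(), q, include_boundary_ties
        )
        for name in POWER_CENTRALITIES
    }
    k = int(q * n)
    top = TopSets(q=q, sets=sets, k=k)
    power_ids = set.intersection(*sets.values()) if sets else set()
    denom = min(len(s) for s in sets.values()) or 1
    four_way = 100.0 * len(power_ids) / denom
    result = PowerResult(
        power_ids=power_ids,
        pairwise_overlap_pct=pairwise_overlap(top),
        four_way_overlap_pct=four_way,
        power_fraction=len(power_ids) / n,
        q=q,
        n=n,
    )
    return top, result


def rich_club_set(connectome: Connectome, degree_threshold: int = 37) -> set[str]:
    """Nodes with total degree strictly above a fixed threshold.

    The comparison class from the adult-fly literature: a degree-only
    criterion, unlike the four-centrality power-neuron definition.
    """
    if degree_threshold < 0:
        raise ValidationError("degree threshold must be >= 0")
    return {
        node
        for node, deg in connectome.graph.degree()
        if deg > degree_threshold
    }


def backbone_subnetwork(connectome: Connectome, ids: Iterable[str]) -> Connectome:
    """Subnetwork induced by ``ids`` (typically the power neurons)."""
    return connectome.induced_subgraph(ids)


@dataclass
class BackboneReport:
    full: NetworkSummary
    backbone: NetworkSummary
    ratios: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        full = self.full.to_frame().T.rename(columns={0: "complete network"})
        back = self.backbone.to_frame().T.rename(columns={0: "power-neuron subnetwork"})
        return full.join(back)


def backbone_report(
    connectome: Connectome,
    power_ids: Iterable[str],
    conventions: CentralityConventions | None = None,
) -> BackboneReport:
    """Compare the full network with the power-neuron induced subnetwork.

    Ratios (backbone / full) are reported for density and normalized
    average degree — the two size-corrected quantities whose increase is
    the signature of a densely interconnected backbone.
    """
    power_ids = set(power_ids)
    if not power_ids:
        raise ValidationError("power_ids must be non-empty for a backbone report")
    full = summarize(connectome, conventions)
    backbone = summarize(backbone_subnetwork(connectome, power_ids), conventions)
    ratios = {
        "density": backbone.density / full.density if full.density else float("nan"),
        "normalized_avg_degree": (
            backbone.normalized_avg_degree / full.normalized_avg_degree
            if full.normalized_avg_degree
            else float("nan")
        ),
    }
    return BackboneReport(full=full, backbone=backbone, ratios=ratios)


def degree_comparison_table(
    centralities: pd.DataFrame, power_ids: Iterable[str]
) -> pd.DataFrame:
    """Mean/median of degree, in-degree and out-degree, all vs power neurons."""
    power_ids = sorted(set(power_ids))
    subset = centralities.loc[power_ids]
    rows = []
    for label, table in (("all neurons", centralities), ("power neurons", subset)):
        row = {"population": label, "n": len(table)}
        for col in ("degree", "in_degree", "out_degree"):
            row[f"{col}_mean"] = float(table[col].mean())
            row[f"{col}_median"] = float(table[col].median())
        rows.append(row)
    return pd.DataFrame(rows)
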