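"""Connectome motifs around core neurons, census, and QAP significance.

The motif of a core neuron collapses its in- and out-neighborhoods onto
neuronal groups: the signature (core group, input-group set, output-group
set) abstracts away which particular neurons are wired, keeping only which
groups feed and are fed by the core. The census counts how many distinct
core neurons (here: power neurons) produce each signature.

Significance uses the Quadratic Assignment Procedure: node group labels
are permuted uniformly while the graph structure — and hence the
structure-derived core set — stays fixed, the census is recomputed on each
of the N null labelings, and the p-value of a motif with observed count
gamma is the fraction of null counts strictly greater than gamma:

    p = (1/N) * sum_j 1[gamma_j > gamma]

The strict inequality follows the test's definition and admits p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Connectome, ValidationError


@dataclass(frozen=True)
class ConnectomeMotif:
    """Motif signature; identity depends only on the three group fields."""

    core_group: str
    in_groups: frozenset[str]
    out_groups: frozenset[str]

    def sort_key(self) -> tuple:
        return (self.core_group, tuple(sorted(self.in_groups)), tuple(sorted(self.out_groups)))

    def describe(self) -> dict[str, str]:
        return {
            "Core group": self.core_group,
            "Input": ", ".join(sorted(self.in_groups)),
            "Output": ", ".join(sorted(self.out_groups)),
        }


@dataclass
class MotifObservation:
    """One core neuron's motif with raw per-group distinct-neighbor counts."""

    motif: ConnectomeMotif | None
    core_id: str
    in_counts: dict[str, int] = field(default_factory=dict)
    out_counts: dict[str, int] = field(default_factory=dict)
    null_in_neighbors: int = 0  # unlabeled neighbors, invisible to the motif
    null_out_neighbors: int = 0


@dataclass
class MotifStats:
    motif: ConnectomeMotif
    count: int
    core_ids: set[str]
    mean_in_connections: dict[str, float]
    mean_out_connections: dict[str, float]


@dataclass
class QAPResult:
    motif: ConnectomeMotif
    gamma_obs: int
    null_counts: list[int]
    n_permutations: int
    p_value: float
    seed: int | None = None


def qap_p_value(gamma_obs: int, null_counts: list[int] | np.ndarray) -> float:
    """Fraction of null counts strictly exceeding the observed count."""
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValidationError("null_counts must be non-empty")
    return float(np.count_nonzero(null_counts > gamma_obs) / null_counts.size)


def build_motif(connectome: Connectome, core_id: str) -> MotifObservation:
    """Motif of one core neuron, or a ``None`` motif if its group is null.

    Unlabeled (group-null) neighbors do not contribute input/output groups;
    they are tallied separately for diagnostics. Per-group counts are
    numbers of distinct neighbors, parallel connections having been
    collapsed at load time.
    """
    rec = connectome.record(core_id)
    graph = connectome.graph
    null_in = null_out = 0
    in_counts: dict[str, int] = {}
    out_counts: dict[str, int] = {}
    for nbr in graph.predecessors(core_id):
        g = connectome.record(nbr).group
        if g is None:
            null_in += 1
        else:
            in_counts[g] = in_counts.get(g, 0) + 1
    for nbr in graph.successors(core_id):
        g = connectome.record(nbr).group
        if g is None:
            null_out += 1
        else:
            out_counts[g] = out_counts.get(g, 0) + 1
    if rec.group is None:
        motif = None
    else:
        motif = ConnectomeMotif(
            rec.group, frozenset(in_counts), frozenset(out_counts)
        )
    return MotifObservation(motif, core_id, in_counts, out_counts, null_in, null_out)


def motif_census(connectome: Connectome, core_ids: set[str]) -> list[MotifStats]:
    """Group identical motif signatures over the core set.

    The count of a motif is the number of distinct cores producing it; mean
    connection counts average the raw per-group distinct-neighbor counts
    over those occurrences. Output order is deterministic (count descending,
    then lexicographic signature).
    """
    observations: dict[ConnectomeMotif, list[MotifObservation]] = {}
    for core_id in sorted(core_ids):
        obs = build_motif(connectome, core_id)
        if obs.motif is None:
            continue
        observations.setdefault(obs.motif, []).append(obs)
    stats = []
    for motif, obs_list in observations.items():
        mean_in = {
            g: float(np.mean([o.in_counts[g] for o in obs_list]))
            for g in motif.in_groups
        }
        mean_out = {
            g: float(np.mean([o.out_counts[g] for o in obs_list]))
            for g in motif.out_groups
        }
        stats.append(
            MotifStats(
                motif=motif,
                count=len(obs_list),
                core_ids={o.core_id for o in obs_list},
                mean_in_connections=mean_in,
                mean_out_connections=mean_out,
            )
        )
    stats.sort(key=lambda s: (-s.count, s.motif.sort_key()))
    return stats


def _indexed_structure(connectome: Connectome, core_ids: set[str]):
    """Integer-coded labels and neighbor index arrays for fast relabeling."""
    nodelist = connectome.node_ids()
    index = {node: i for i, node in enumerate(nodelist)}
    group_names = sorted(connectome.groups())
    group_code = {g: i for i, g in enumerate(group_names)}
    labels = np.array(
        [
            group_code.get(connectome.record(node).group, -1)
            for node in nodelist
        ],
        dtype=np.int64,
    )
    graph = connectome.graph
    cores = sorted(index[c] for c in core_ids)
    in_nbrs = {
        c: np.fromiter(
            (index[p] for p in graph.predecessors(nodelist[c])), dtype=np.int64
        )
        for c in cores
    }
    out_nbrs = {
        c: np.fromiter(
            (index[s] for s in graph.successors(nodelist[c])), dtype=np.int64
        )
        for c in cores
    }
    return nodelist, group_names, labels, cores, in_nbrs, out_nbrs


def _coded_census(labels, cores, in_nbrs, out_nbrs) -> dict[tuple, int]:
    counts: dict[tuple, int] = {}
    for c in cores:
        g = labels[c]
        if g < 0:
            continue
        ins = labels[in_nbrs[c]] if in_nbrs[c].size else labels[:0]
        outs = labels[out_nbrs[c]] if out_nbrs[c].size else labels[:0]
        key = (
            int(g),
            frozenset(int(x) for x in np.unique(ins[ins >= 0])),
            frozenset(int(x) for x in np.unique(outs[outs >= 0])),
        )
        counts[key] = counts.get(key, 0) + 1
    return counts


def qap_test(
    connectome: Connectome,
    core_ids: set[str],
    census: list[MotifStats],
    n_permutations: int = 1000,
    seed: int | None = None,
    shuffle_scope: str = "all",
) -> list[QAPResult]:
    """QAP label-permutation test for every motif in the census.

    Group labels are shuffled uniformly over all nodes (``shuffle_scope=
    "all"``, null labels participating) or over labeled nodes only
    (``"labeled_only"``). Core ids stay fixed: power status is derived from
    structure, which the permutation preserves. Deterministic given
    ``seed``.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if shuffle_scope not in ("all", "labeled_only"):
        raise ValidationError(f"unknown shuffle scope {shuffle_scope!r}")
    rng = np.random.default_rng(seed)
    _, group_names, labels, cores, in_nbrs, out_nbrs = _indexed_structure(
        connectome, core_ids
    )
    group_code = {g: i for i, g in enumerate(group_names)}

    def encode(motif: ConnectomeMotif) -> tuple:
        return (
            group_code[motif.core_group],
            frozenset(group_code[g] for g in motif.in_groups),
            frozenset(group_code[g] for g in motif.out_groups),
        )

    observed = {encode(s.motif): s for s in census}
    null_counts = {key: np.zeros(n_permutations, dtype=np.int64) for key in observed}
    labeled_positions = np.flatnonzero(labels >= 0)
    for j in range(n_permutations):
        if shuffle_scope == "all":
            permuted = labels[rng.permutation(labels.size)]
        else:
            permuted = labels.copy()
            permuted[labeled_positions] = labels[
                labeled_positions[rng.permutation(labeled_positions.size)]
            ]
        for key, count in _coded_census(permuted, cores, in_nbrs, out_nbrs).items():
            if key in null_counts:
                null_counts[key][j] = count
    results = []
    for key, stats in observed.items():
        nulls = null_counts[key]
        results.append(
            QAPResult(
                motif=stats.motif,
                gamma_obs=stats.count,
                null_counts=nulls.tolist(),
                n_permutations=n_permutations,
                p_value=qap_p_value(stats.count, nulls),
                seed=seed,
            )
        )
    results.sort(key=lambda r: (-r.gamma_obs, r.motif.sort_key()))
    return results


def filter_frequent(
    census: list[MotifStats],
    qap: list[QAPResult],
    min_count: int,
    alpha: float = 0.05,
) -> list[MotifStats]:
    """Motifs that are both significant (p < alpha) and frequent (count >= min_count)."""
    census_keys = {s.motif for s in census}
    qap_keys = {r.motif for r in qap}
    if census_keys != qap_keys:
        raise ValidationError("census and QAP results cover different motif sets")
    p_by_motif = {r.motif: r.p_value for r in qap}
    kept = [
        s
        for s in census
        if s.count >= min_count and p_by_motif[s.motif] < alpha
    ]
    kept.sort(key=lambda s: (-s.count, s.motif.sort_key()))
    return kept


def sensitivity_scan(
    census: list[MotifStats],
    qap: list[QAPResult],
    thresholds: list[int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Retained-motif counts across ascending frequency thresholds.

    Used to choose the minimum-frequency cutoff: the retained count is
    non-increasing in the threshold, and a knee in the curve separates
    robust motifs from noise.
    """
    if not thresholds:
        raise ValidationError("thresholds must be non-empty")
    if list(thresholds) != sorted(thresholds):
        raise ValidationError("thresholds must be ascending")
    rows = [
        {
            "min_count": t,
            "n_retained": len(filter_frequent(census, qap, t, alpha)),
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def census_to_frame(census: list[MotifStats], qap: list[QAPResult] | None = None) -> pd.DataFrame:
    """Census (optionally with p-values) in the standard table layout."""
    p_by_motif = {r.motif: r.p_value for r in qap} if qap else {}
    rows = []
    for s in census:
        row = s.motif.describe()
        row["Count"] = s.count
        if p_by_motif:
            row["p-value"] = p_by_motif.get(s.motif)
        rows.append(row)
    return pd.DataFrame(rows)


def mean_connections_frame(census: list[MotifStats]) -> pd.DataFrame:
    """Per-motif mean distinct-connection counts, one row per group and role."""
    rows = []
    for rank, s in enumerate(census, start=1):
        for group, mean in sorted(s.mean_in_connections.items()):
            rows.append(
                {
                    "motif_rank": rank,
                    "Core group": s.motif.core_group,
                    "role": "input",
                    "group": group,
                    "mean_connections": mean,
                }
            )
        for group, mean in sorted(s.mean_out_connections.items()):
            rows.append(
                {
                    "motif_rank": rank,
                    "Core group": s.motif.core_group,
                    "role": "output",
                    "group": group,
                    "mean_connections": mean,
                }
            )
    return pd.DataFrame(rows)
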