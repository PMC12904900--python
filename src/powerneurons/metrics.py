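"""Whole-network summaries and the four node centralities.

Directed-graph conventions are explicit and configurable because the
quantities they affect (closeness direction, eigenvector edge convention,
path-metric scope, clustering projection) are not uniquely determined by
the standard textbook definitions on graphs that are directed and not
strongly connected. Defaults:

* closeness — outward directed distances with the reachable-set
  (Wasserman–Faust) correction: ``(r-1)^2 / ((n-1) * sum of distances)``
  over the ``r-1`` reachable nodes, 0 when nothing is reachable;
* betweenness — exact directed Brandes over all ordered pairs, endpoints
  excluded, unnormalized;
* eigenvector — in-edge convention (a node is central when central nodes
  point to it), computed per weakly connected component;
* path length / diameter — over directed shortest paths within the largest
  strongly connected component;
* clustering — on the undirected projection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph as csgraph
import scipy.stats

from .model import Connectome, ConvergenceError, ValidationError

try:  # exact same algorithm, C implementation; networkx fallback below
    import igraph as _igraph
except ImportError:  # pragma: no cover - igraph is an ordinary dependency
    _igraph = None

CENTRALITY_NAMES = ("degree", "closeness", "betweenness", "eigenvector")


# -- elementary bookkeeping formulas ---------------------------------------
# Exposed separately so size-only identities can be checked without a graph.

def average_degree(n_nodes: int, n_arcs: int) -> float:
    """Mean total degree, 2m/n."""
    return 2.0 * n_arcs / n_nodes


def normalized_average_degree(n_nodes: int, n_arcs: int) -> float:
    """Mean total degree divided by network size, 2m/n^2."""
    return average_degree(n_nodes, n_arcs) / n_nodes


def density(n_nodes: int, n_arcs: int) -> float:
    """Directed density m / (n(n-1)), self-loops excluded by the model."""
    if n_nodes < 2:
        return 0.0
    return n_arcs / (n_nodes * (n_nodes - 1))


@dataclass
class NetworkSummary:
    n_nodes: int
    n_arcs: int
    avg_degree: float
    normalized_avg_degree: float
    density: float
    avg_clustering: float
    avg_path_length: float
    diameter: float
    degree_assortativity: float
    max_scc_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


@dataclass
class PathMetrics:
    avg_path_length: float
    diameter: float
    component_size: int
    defined: bool = True


@dataclass
class CentralityConventions:
    """Convention flags; all recorded in the run manifest."""

    closeness_direction: str = "out"  # or "in"
    eigenvector_direction: str = "in"  # or "out"
    clustering_mode: str = "undirected"
    path_metric_scope: str = "largest_scc"  # or "undirected"
    betweenness_backend: str = "auto"  # auto | igraph | networkx
    eigenvector_tol: float = 1e-10
    eigenvector_max_iter: int = 1000

    def to_dict(self) -> dict:
        return asdict(self)


def _adjacency(connectome: Connectome, nodelist: list[str]) -> scipy.sparse.csr_array:
    return nx.to_scipy_sparse_array(
        connectome.graph, nodelist=nodelist, weight=None, format="csr"
    )


def _distance_matrix(adj: scipy.sparse.csr_array) -> np.ndarray:
    """All-pairs directed BFS distances; inf where unreachable."""
    return csgraph.shortest_path(adj, method="D", directed=True, unweighted=True)


# -- centralities -----------------------------------------------------------

def closeness_from_distances(dist: np.ndarray) -> np.ndarray:
    """Wasserman–Faust corrected closeness from a row-wise distance matrix.

    Row v holds distances from v to every node; the caller chooses the
    direction by orienting the matrix.
    """
    n = dist.shape[0]
    if n <= 1:
        return np.zeros(n)
    finite = np.isfinite(dist)
    np.fill_diagonal(finite, False)
    reach = finite.sum(axis=1).astype(float)  # r - 1
    totals = np.where(finite, dist, 0.0).sum(axis=1)
    out = np.zeros(n)
    nonzero = totals > 0
    out[nonzero] = reach[nonzero] ** 2 / ((n - 1) * totals[nonzero])
    return out


def _betweenness(
    connectome: Connectome, nodelist: list[str], backend: str
) -> np.ndarray:
    use_igraph = backend == "igraph" or (backend == "auto" and _igraph is not None)
    if backend not in ("auto", "igraph", "networkx"):
        raise ValidationError(f"unknown betweenness backend {backend!r}")
    if use_igraph:
        if _igraph is None:
            raise ValidationError("igraph backend requested but igraph is missing")
        index = {node: i for i, node in enumerate(nodelist)}
        g = _igraph.Graph(
            n=len(nodelist),
            edges=[(index[u], index[v]) for u, v in connectome.graph.edges],
            directed=True,
        )
        return np.asarray(g.betweenness(directed=True), dtype=float)
    raw = nx.betweenness_centrality(connectome.graph, normalized=False)
    return np.array([raw[node] for node in nodelist])


def betweenness(connectome: Connectome, backend: str = "auto") -> pd.Series:
    """Exact directed Brandes betweenness (unnormalized, endpoints excluded)."""
    nodelist = connectome.node_ids()
    return pd.Series(
        _betweenness(connectome, nodelist, backend),
        index=pd.Index(nodelist, name="id"),
        name="betweenness",
    )


def eigenvector_by_component(
    connectome: Connectome,
    nodelist: list[str],
    direction: str = "in",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Dominant-eigenvector centrality per weakly connected component.

    Power iteration runs on ``A^T + I`` (in-edge convention) or ``A + I``;
    the identity shift leaves eigenvectors unchanged while guaranteeing
    convergence on periodic components such as pure directed cycles. Each
    component's vector is scaled to unit maximum. Acyclic components have
    spectral radius zero and receive all-zero values.
    """
    if direction not in ("in", "out"):
        raise ValidationError(f"eigenvector direction must be in/out, got {direction!r}")
    index = {node: i for i, node in enumerate(nodelist)}
    values = np.zeros(len(nodelist))
    for comp_nodes in nx.weakly_connected_components(connectome.graph):
        comp = sorted(comp_nodes)
        sub = connectome.graph.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        if nx.is_directed_acyclic_graph(sub):
            continue  # nilpotent adjacency: no Perron eigenvector
        adj = nx.to_scipy_sparse_array(sub, nodelist=comp, weight=None, format="csr")
        mat = adj.T if direction == "in" else adj
        x = np.ones(len(comp))
        converged = False
        for _ in range(max_iter):
            x_new = mat @ x + x
            x_new /= x_new.max()
            if np.abs(x_new - x).max() < tol:
                x = x_new
                converged = True
                break
            x = x_new
        if not converged:
            raise ConvergenceError(
                f"eigenvector power iteration did not converge on the "
                f"{len(comp)}-node component containing {comp[0]!r}"
            )
        for node, value in zip(comp, x):
            values[index[node]] = value
    return values


def compute_centralities(
    connectome: Connectome,
    conventions: CentralityConventions | None = None,
) -> pd.DataFrame:
    """Per-node in/out/total degree, closeness, betweenness, eigenvector.

    Returns a DataFrame indexed by node id with columns ``in_degree``,
    ``out_degree``, ``degree``, ``closeness``, ``betweenness``,
    ``eigenvector``.
    """
    if connectome.n_nodes == 0:
        raise ValidationError("cannot compute centralities of an empty connectome")
    conv = conventions or CentralityConventions()
    nodelist = connectome.node_ids()
    graph = connectome.graph

    in_deg = np.array([graph.in_degree(v) for v in nodelist], dtype=int)
    out_deg = np.array([graph.out_degree(v) for v in nodelist], dtype=int)

    adj = _adjacency(connectome, nodelist)
    dist = _distance_matrix(adj)
    if conv.closeness_direction == "out":
        closeness = closeness_from_distances(dist)
    elif conv.closeness_direction == "in":
        closeness = closeness_from_distances(dist.T)
    else:
        raise ValidationError(
            f"closeness_direction must be in/out, got {conv.closeness_direction!r}"
        )

    betweenness = _betweenness(connectome, nodelist, conv.betweenness_backend)
    eigenvector = eigenvector_by_component(
        connectome,
        nodelist,
        direction=conv.eigenvector_direction,
        tol=conv.eigenvector_tol,
        max_iter=conv.eigenvector_max_iter,
    )
    return pd.DataFrame(
        {
            "in_degree": in_deg,
            "out_degree": out_deg,
            "degree": in_deg + out_deg,
            "closeness": closeness,
            "betweenness": betweenness,
            "eigenvector": eigenvector,
        },
        index=pd.Index(nodelist, name="id"),
    )


# -- whole-network summaries ------------------------------------------------

def _largest_scc(connectome: Connectome) -> list[str]:
    return sorted(max(nx.strongly_connected_components(connectome.graph), key=len))


def path_metrics(
    connectome: Connectome, scope: str = "largest_scc"
) -> PathMetrics:
    """Average shortest path length and diameter.

    Computed over directed BFS distances within the largest strongly
    connected component (default), or over the undirected projection's
    largest component. Degenerate graphs (no component with >= 2 nodes)
    yield a flagged undefined result rather than an exception.
    """
    if scope == "largest_scc":
        comp = _largest_scc(connectome)
        graph = connectome.graph.subgraph(comp)
        directed = True
    elif scope == "undirected":
        und = connectome.graph.to_undirected(as_view=True)
        comp = sorted(max(nx.connected_components(und), key=len))
        graph = und.subgraph(comp)
        directed = False
    else:
        raise ValidationError(f"unknown path metric scope {scope!r}")
    if len(comp) < 2:
        return PathMetrics(float("nan"), float("nan"), len(comp), defined=False)
    adj = nx.to_scipy_sparse_array(graph, nodelist=comp, weight=None, format="csr")
    dist = csgraph.shortest_path(adj, method="D", directed=directed, unweighted=True)
    off_diag = dist[~np.eye(len(comp), dtype=bool)]
    finite = off_diag[np.isfinite(off_diag)]
    return PathMetrics(float(finite.mean()), float(finite.max()), len(comp))


def total_degree_assortativity(connectome: Connectome) -> float:
    """Pearson correlation of endpoint total degrees over arcs; NaN if degenerate."""
    edges = list(connectome.graph.edges)
    if not edges:
        return float("nan")
    deg = dict(connectome.graph.degree())  # total degree on a DiGraph
    x = np.array([deg[u] for u, _ in edges], dtype=float)
    y = np.array([deg[v] for _, v in edges], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(scipy.stats.pearsonr(x, y)[0])


def summarize(
    connectome: Connectome, conventions: CentralityConventions | None = None
) -> NetworkSummary:
    """Basic whole-network features (size, density, clustering, paths, ...)."""
    if connectome.n_nodes == 0:
        raise ValidationError("cannot summarize an empty connectome")
    conv = conventions or CentralityConventions()
    n, m = connectome.n_nodes, connectome.n_arcs
    paths = path_metrics(connectome, scope=conv.path_metric_scope)
    clustering = nx.average_clustering(connectome.graph.to_undirected(as_view=False))
    scc_size = len(_largest_scc(connectome)) if m else 1
    return NetworkSummary(
        n_nodes=n,
        n_arcs=m,
        avg_degree=average_degree(n, m),
        normalized_avg_degree=normalized_average_degree(n, m),
        density=density(n, m),
        avg_clustering=float(clustering),
        avg_path_length=paths.avg_path_length,
        diameter=paths.diameter,
        degree_assortativity=total_degree_assortativity(connectome),
        max_scc_size=scc_size,
    )
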