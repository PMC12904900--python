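"""Reading raw connectome exports and writing result tables and graphs.

Supported arc inputs: header CSV/TSV edge lists (``source,target[,weight]``),
Matrix Market coordinate files (paired with a one-id-per-line index file),
and dense CSV adjacency matrices with id headers. Node metadata comes from
a CSV/TSV table with a configurable column mapping. Connection weights are
synapse counts in the source data; the graph model binarizes them (an arc
exists iff total weight > 0).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import scipy.io
import scipy.sparse

from .model import (
    ConfigurationError,
    Connectome,
    FormatError,
    LoadReport,
    NodeRecord,
    ValidationError,
    normalize_side,
)

ARC_FORMATS = ("edge_csv", "matrix_market", "dense_csv")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_arc_list(
    path: str | Path,
    format: str = "edge_csv",
    ids_path: str | Path | None = None,
) -> list[tuple[str, str, float]]:
    """Read raw arcs as (source, target, weight) triples.

    ``matrix_market`` needs ``ids_path``, a text file with one node id per
    line giving the row/column order; without it, 0-based indices become
    the ids. A missing weight column in ``edge_csv`` defaults every weight
    to 1. Negative weights are rejected.
    """
    path = Path(path)
    if format not in ARC_FORMATS:
        raise ConfigurationError(
            f"unknown arc format {format!r}; expected one of {ARC_FORMATS}"
        )
    if not path.exists():
        raise FormatError(f"arc file not found: {path}")

    if format == "edge_csv":
        return _read_edge_csv(path)
    if format == "matrix_market":
        return _read_matrix_market(path, ids_path)
    return _read_dense_csv(path)


def _check_weight(weight: float, where: str) -> float:
    if weight < 0:
        raise ValidationError(f"negative weight at {where}: {weight}")
    return weight


def _read_edge_csv(path: Path) -> list[tuple[str, str, float]]:
    frame = _read_table(path)
    cols = {c.strip().lower(): c for c in frame.columns}
    if "source" not in cols or "target" not in cols:
        raise FormatError(
            f"{path}: edge list must have 'source' and 'target' header columns"
        )
    triples: list[tuple[str, str, float]] = []
    weight_col = cols.get("weight")
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        src = str(row[frame.columns.get_loc(cols["source"])])
        tgt = str(row[frame.columns.get_loc(cols["target"])])
        if not src or not tgt:
            raise FormatError(f"{path}:{i}: empty source or target id")
        if weight_col is not None:
            raw = row[frame.columns.get_loc(weight_col)]
            try:
                weight = float(raw) if raw != "" else 1.0
            except ValueError:
                raise FormatError(f"{path}:{i}: non-numeric weight {raw!r}") from None
        else:
            weight = 1.0
        triples.append((src, tgt, _check_weight(weight, f"{path}:{i}")))
    return triples


def _read_matrix_market(
    path: Path, ids_path: str | Path | None
) -> list[tuple[str, str, float]]:
    try:
        matrix = scipy.io.mmread(path)
    except Exception as exc:
        raise FormatError(f"cannot parse Matrix Market file {path}: {exc}") from exc
    matrix = scipy.sparse.coo_matrix(matrix)
    if ids_path is not None:
        ids = [
            line.strip()
            for line in Path(ids_path).read_text().splitlines()
            if line.strip()
        ]
        if len(ids) < max(matrix.shape):
            raise FormatError(
                f"id index {ids_path} has {len(ids)} ids for a "
                f"{matrix.shape} matrix"
            )
    else:
        ids = [str(i) for i in range(max(matrix.shape))]
    triples = []
    for r, c, w in zip(matrix.row, matrix.col, matrix.data):
        if w != 0:
            triples.append(
                (ids[r], ids[c], _check_weight(float(w), f"{path} entry ({r},{c})"))
            )
    return triples


def _read_dense_csv(path: Path) -> list[tuple[str, str, float]]:
    frame = _read_table(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: dense matrix needs an id column plus values")
    row_ids = frame.iloc[:, 0].astype(str).tolist()
    col_ids = [str(c) for c in frame.columns[1:]]
    triples = []
    for r, row_id in enumerate(row_ids):
        for c, col_id in enumerate(col_ids):
            raw = frame.iat[r, c + 1]
            try:
                weight = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric entry {raw!r} at ({row_id},{col_id})"
                ) from None
            if weight != 0:
                triples.append(
                    (row_id, col_id, _check_weight(weight, f"{path} ({row_id},{col_id})"))
                )
    return triples


def read_node_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[NodeRecord]:
    """Read node metadata into :class:`NodeRecord` objects.

    ``column_map`` maps semantic roles (``id``, ``group``, ``side``,
    ``homolog``) onto column names; only ``id`` is required. Columns not
    claimed by the map become ``extra`` attributes in file order. Side
    strings are normalized case-insensitively; empty group cells become
    ``None``.
    """
    column_map = dict(column_map or {})
    frame = _read_table(path)
    id_col = column_map.get("id", "id")
    if id_col not in frame.columns:
        raise ConfigurationError(
            f"{path}: no id column {id_col!r} (columns: {list(frame.columns)})"
        )
    group_col = column_map.get("group")
    side_col = column_map.get("side")
    homolog_col = column_map.get("homolog")
    for role, col in (("group", group_col), ("side", side_col), ("homolog", homolog_col)):
        if col is not None and col not in frame.columns:
            raise ConfigurationError(f"{path}: mapped {role} column {col!r} missing")
    claimed = {id_col, group_col, side_col, homolog_col} - {None}
    extra_cols = [c for c in frame.columns if c not in claimed]

    records = []
    for row in frame.itertuples(index=False):
        def cell(col: str | None) -> str:
            return str(row[frame.columns.get_loc(col)]).strip() if col else ""

        group = cell(group_col) or None
        homolog = cell(homolog_col) or None
        records.append(
            NodeRecord(
                id=cell(id_col),
                group=group,
                side=normalize_side(cell(side_col) or None),
                homolog_id=homolog,
                extra={c: cell(c) for c in extra_cols},
            )
        )
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    duplicates = sorted(i for i, n in seen.items() if n > 1)
    if duplicates:
        raise ValidationError(f"duplicate node ids in {path}: {duplicates}")
    return records


def build_connectome(
    arc_triples: Iterable[tuple[str, str, float]],
    node_records: Sequence[NodeRecord],
    stage_label: str = "unnamed",
    strict: bool = True,
) -> tuple[Connectome, LoadReport]:
    """Assemble the binarized simple digraph from raw triples and metadata.

    An arc exists iff at least one triple with weight > 0 links the ordered
    pair; self-loops are dropped and counted; parallel connections collapse
    to one arc. Nodes present only in the node table are kept as isolated
    nodes. Arcs with endpoints missing from the node table raise in strict
    mode (default) or create group-null side-unknown records in lenient
    mode; either way they are tallied in the :class:`LoadReport`.
    """
    if not node_records:
        raise ValidationError("node_records must be non-empty")
    connectome = Connectome(stage_label)
    for rec in node_records:
        connectome.add_node(rec)
    report = LoadReport()

    seen_pairs: set[tuple[str, str]] = set()
    for src, tgt, weight in arc_triples:
        if weight < 0:
            raise ValidationError(f"negative weight on arc ({src},{tgt}): {weight}")
        if weight == 0:
            report.zero_weight_dropped += 1
            continue
        if src == tgt:
            report.self_loops_dropped += 1
            continue
        missing = [e for e in (src, tgt) if e not in connectome.graph]
        if missing:
            report.unknown_endpoint_arcs += 1
            if strict:
                raise ValidationError(
                    f"arc ({src},{tgt}) references unknown node(s) {missing}; "
                    "use strict=False to create placeholder records"
                )
            for node_id in missing:
                connectome.add_node(NodeRecord(id=node_id))
                report.nodes_created_lenient += 1
        if (src, tgt) in seen_pairs:
            report.duplicate_arcs_merged += 1
            continue
        seen_pairs.add((src, tgt))
        connectome.add_arc(src, tgt)
    return connectome, report


# -- output -----------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Write a result table; ``csv`` and ``json`` round-trip losslessly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "json":
        frame.to_json(path, orient="records", indent=2)
    else:
        raise ConfigurationError(f"unknown table format {format!r}")
    return path


def write_graphml(graph: nx.Graph, path: str | Path) -> Path:
    """Write a (group) graph as GraphML with all node/edge attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)
    return path


def write_manifest(manifest: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def write_connectome(
    connectome: Connectome, directory: str | Path, prefix: str = "connectome"
) -> dict[str, Path]:
    """Export a connectome as the same edge-list + node-table CSVs it loads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arc_frame = pd.DataFrame(
        connectome.to_arc_triples(), columns=["source", "target", "weight"]
    )
    rows = []
    for rec in connectome.records():
        row = {
            "id": rec.id,
            "group": rec.group or "",
            "side": rec.side,
            "homolog": rec.homolog_id or "",
        }
        row.update(rec.extra)
        rows.append(row)
    node_frame = pd.DataFrame(rows)
    arcs_path = write_table(arc_frame, directory / f"{prefix}_arcs.csv")
    nodes_path = write_table(node_frame, directory / f"{prefix}_nodes.csv")
    return {"arcs": arcs_path, "nodes": nodes_path}


def read_connectome(
    arcs_path: str | Path,
    nodes_path: str | Path,
    stage_label: str = "unnamed",
    strict: bool = True,
) -> tuple[Connectome, LoadReport]:
    """Convenience loader: edge CSV + node table -> Connectome."""
    triples = read_arc_list(arcs_path, format="edge_csv")
    records = read_node_table(
        nodes_path, {"id": "id", "group": "group", "side": "side", "homolog": "homolog"}
    )
    return build_connectome(triples, records, stage_label, strict=strict)
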