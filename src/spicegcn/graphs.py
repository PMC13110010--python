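"""Radius-neighborhood tissue graphs with polar/spherical edge attributes.

Cells are nodes; a bidirectional edge connects every pair of cells strictly
closer than the neighborhood radius ``r`` (in µm). Each directed edge carries
a pseudo-coordinate vector describing the displacement from the target cell to
its neighbor: ``(distance, angle)`` in 2D, ``(distance, azimuth, inclination)``
in 3D. These edge attributes are the inputs of the Gaussian kernels in the
convolution operator.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import CellTable, DataSplit, GeneRoleMap, ValidationError

__all__ = [
    "TissueGraph",
    "radius_edges",
    "compute_edge_attributes",
    "build_radius_graph",
    "build_dataset",
    "save_graph",
    "load_graph",
]


@dataclass
class TissueGraph:
    """One slice (or spatial tile) of cells as a graph.

    ``edge_index`` is a ``(2, E)`` integer array of directed edges
    ``(source, target)``; messages flow from source to target. Edges appear in
    both directions and are sorted lexicographically by (source, target).
    """

    node_ids: np.ndarray  # (n,) cell ids
    positions: np.ndarray  # (n, 2|3) µm
    features: np.ndarray  # (n, d0) predictor matrix
    targets: np.ndarray  # (n, G) response matrix
    edge_index: np.ndarray  # (2, E) int
    edge_attr: np.ndarray  # (E, a)
    radius: float
    feature_names: list[str] = field(default_factory=list)
    response_names: list[str] = field(default_factory=list)
    slice_id: str = ""
    group: str = ""

    def __post_init__(self):
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(2, -1)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        attr = np.asarray(self.edge_attr, dtype=float)
        if attr.size == 0:
            attr = attr.reshape(0, attr.shape[-1] if attr.ndim > 1 else 2)
        attr = np.atleast_2d(attr)
        if attr.shape[0] != self.edge_index.shape[1]:
            raise ValidationError(
                f"edge attribute rows ({attr.shape[0]}) != edge count "
                f"({self.edge_index.shape[1]})"
            )
        self.edge_attr = attr
        if self.edge_index.size and self.edge_index.max() >= self.n_nodes:
            raise ValidationError("edge references a missing node")

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_index[1], minlength=self.n_nodes).astype(float)


def radius_edges(positions: np.ndarray, r: float) -> tuple[np.ndarray, np.ndarray]:
    """All directed pairs with ``0 < d(i, j) < r`` (strict), plus their distances.

    Returns ``(edge_index, distances)`` with edges sorted by (source, target).
    Uses a k-d tree; equivalent to the O(n^2) pairwise scan.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n == 0:
        raise ValidationError("empty cell set")
    if r < 0:
        raise ValidationError("radius must be non-negative")
    if r == 0 or n == 1:
        return np.zeros((2, 0), dtype=np.int64), np.zeros(0)
    pairs = cKDTree(positions).query_pairs(r, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
        strict = d < r  # query_pairs includes ties at exactly r
        pairs, d = pairs[strict], d[strict]
    else:
        d = np.zeros(0)
    if (np.asarray(d) == 0).any():
        raise ValidationError("coincident cells produce zero-length edges")
    src = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.zeros(0, int)
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.zeros(0, int)
    dd = np.concatenate([d, d]) if len(pairs) else np.zeros(0)
    order = np.lexsort((dst, src))
    return np.stack([src[order], dst[order]]).astype(np.int64), dd[order]


def compute_edge_attributes(
    positions: np.ndarray, edge_index: np.ndarray, mode: str | None = None
) -> np.ndarray:
    """Polar (2D) or spherical (3D) pseudo-coordinates for each directed edge.

    For edge (source j, target i) the displacement is from the target to its
    neighbor. 2D rows are ``(distance, angle)`` with the angle from the
    full-quadrant two-argument arctangent in (-pi, pi]; 3D rows are
    ``(distance, azimuth, inclination)`` with inclination in [0, pi].
    """
    positions = np.asarray(positions, dtype=float)
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    dim = positions.shape[1]
    if mode is None:
        mode = "polar2d" if dim == 2 else "spherical3d"
    if (mode == "polar2d") != (dim == 2):
        raise ValidationError(f"mode {mode!r} does not match {dim}D coordinates")
    src, dst = edge_index
    disp = positions[src] - positions[dst]
    dist = np.linalg.norm(disp, axis=1)
    if (dist == 0).any():
        raise ValidationError("zero-length displacement on an edge (self-edge?)")
    azim = np.arctan2(disp[:, 1], disp[:, 0])
    azim = np.where(azim <= -np.pi, azim + 2 * np.pi, azim)  # convention: (-pi, pi]
    if mode == "polar2d":
        return np.column_stack([dist, azim])
    incl = np.arccos(np.clip(disp[:, 2] / dist, -1.0, 1.0))
    return np.column_stack([dist, azim, incl])


def _one_hot(values: pd.Series, categories: list[str]) -> np.ndarray:
    """One-hot encode; categories absent from the list map to all-zero rows."""
    idx = {c: i for i, c in enumerate(categories)}
    out = np.zeros((len(values), len(categories)))
    for row, v in enumerate(values.astype(str)):
        j = idx.get(v)
        if j is not None:
            out[row, j] = 1.0
    return out


def build_radius_graph(
    cells: CellTable,
    roles: GeneRoleMap,
    r: float,
    use_cell_types: bool = False,
    cell_type_categories: list[str] | None = None,
    slice_id: str = "",
    group: str = "",
) -> TissueGraph:
    """Build the radius-``r`` graph for the cells of one slice or tile.

    Expects a preprocessed table (log1p predictors). Node features are the
    ligand/receptor columns plus, optionally, a one-hot cell-type encoding;
    targets are the raw response columns.
    """
    if cells.n_cells == 0:
        raise ValidationError("empty cell set")
    positions = cells.positions()
    edge_index, dist = radius_edges(positions, r)
    edge_attr = (
        compute_edge_attributes(positions, edge_index)
        if edge_index.size
        else np.zeros((0, 2 if not cells.is_3d else 3))
    )
    predictors = [g for g in cells.genes if roles.get(g) in ("ligand", "receptor")]
    responses = [g for g in cells.genes if roles.get(g) == "response"]
    X = cells.data[predictors].to_numpy(dtype=float)
    feature_names = list(predictors)
    if use_cell_types:
        if not cells.has_cell_type:
            raise ValidationError("use_cell_types=True but table has no cell_type column")
        if cell_type_categories is None:
            cell_type_categories = sorted(cells.data["cell_type"].astype(str).unique())
        X = np.hstack([X, _one_hot(cells.data["cell_type"], cell_type_categories)])
        feature_names += [f"cell_type={c}" for c in cell_type_categories]
    Y = cells.data[responses].to_numpy(dtype=float)
    return TissueGraph(
        node_ids=cells.data["cell_id"].to_numpy(),
        positions=positions,
        features=X,
        targets=Y,
        edge_index=edge_index,
        edge_attr=edge_attr,
        radius=float(r),
        feature_names=feature_names,
        response_names=list(responses),
        slice_id=slice_id or (cells.data["slice_id"].iloc[0] if cells.n_cells else ""),
        group=group,
    )


def build_dataset(
    cells: CellTable,
    roles: GeneRoleMap,
    split: DataSplit,
    r: float,
    use_cell_types: bool = False,
) -> dict[str, list[TissueGraph]]:
    """Build one graph per (slice, group) for each partition of the split.

    The split's ``group`` column (animal, slice, or spatial tile) defines the
    graph boundaries, so no edge ever crosses a partition. Cell-type
    categories, if used, are fixed from the full table so the encoding is
    consistent across partitions.
    """
    merged = split.frame.merge(cells.data, on=["cell_id", "slice_id"], how="inner")
    if len(merged) != len(split.frame):
        raise ValidationError("split references cells absent from the table")
    if split.mode == "by_group":
        span = merged.groupby("slice_id")["partition"].nunique()
        if (span > 1).any():
            bad = span[span > 1].index.tolist()
            raise ValidationError(f"slices span multiple partitions in by_group mode: {bad}")
    categories = (
        sorted(cells.data["cell_type"].astype(str).unique())
        if use_cell_types and cells.has_cell_type
        else None
    )
    out: dict[str, list[TissueGraph]] = {p: [] for p in ("train", "validation", "test")}
    for (part, slice_id, group), sub in merged.groupby(
        ["partition", "slice_id", "group"], sort=True
    ):
        table = CellTable(sub.drop(columns=["partition", "group"]), genes=cells.genes)
        out[part].append(
            build_radius_graph(
                table,
                roles,
                r,
                use_cell_types=use_cell_types,
                cell_type_categories=categories,
                slice_id=str(slice_id),
                group=str(group),
            )
        )
    return out


def save_graph(graph: TissueGraph, prefix: str | os.PathLike) -> None:
    """Serialize a graph as node/edge tables plus a JSON sidecar."""
    prefix = os.fspath(prefix)
    nodes = pd.DataFrame(graph.positions, columns=list("xyz"[: graph.positions.shape[1]]))
    nodes.insert(0, "cell_id", graph.node_ids)
    for i, name in enumerate(graph.feature_names):
        nodes[f"feat:{name}"] = graph.features[:, i]
    for i, name in enumerate(graph.response_names):
        nodes[f"resp:{name}"] = graph.targets[:, i]
    nodes.to_csv(prefix + ".nodes.csv", index=False)
    edges = pd.DataFrame(
        {"source": graph.edge_index[0], "target": graph.edge_index[1]}
    )
    for i in range(graph.edge_attr.shape[1]):
        edges[f"attr{i}"] = graph.edge_attr[:, i]
    edges.to_csv(prefix + ".edges.csv", index=False)
    meta = {
        "radius": graph.radius,
        "feature_names": graph.feature_names,
        "response_names": graph.response_names,
        "slice_id": graph.slice_id,
        "group": graph.group,
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_graph(prefix: str | os.PathLike) -> TissueGraph:
    prefix = os.fspath(prefix)
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    nodes = pd.read_csv(prefix + ".nodes.csv")
    edges = pd.read_csv(prefix + ".edges.csv")
    coord_cols = [c for c in ("x", "y", "z") if c in nodes.columns]
    attr_cols = [c for c in edges.columns if c.startswith("attr")]
    return TissueGraph(
        node_ids=nodes["cell_id"].astype(str).to_numpy(),
        positions=nodes[coord_cols].to_numpy(dtype=float),
        features=nodes[[f"feat:{n}" for n in meta["feature_names"]]].to_numpy(dtype=float),
        targets=nodes[[f"resp:{n}" for n in meta["response_names"]]].to_numpy(dtype=float),
        edge_index=edges[["source", "target"]].to_numpy(dtype=np.int64).T,
        edge_attr=edges[attr_cols].to_numpy(dtype=float),
        radius=float(meta["radius"]),
        feature_names=meta["feature_names"],
        response_names=meta["response_names"],
        slice_id=meta.get("slice_id", ""),
        group=meta.get("group", ""),
    )
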