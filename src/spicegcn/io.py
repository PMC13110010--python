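"""Cell tables, gene-role maps, preprocessing, and train/validation/test splits.

The on-disk inputs are ordinary spatial single-cell tables: one row per cell
with micron-scale coordinates, a tissue/slice identifier, optional animal and
cell-type annotations, and one column per gene. A companion two-column table
assigns every gene a role -- ligand, receptor, response, or control -- which
determines whether it enters the model as a predictor, a prediction target,
or not at all.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "GeneRoleMap",
    "CellTable",
    "DataSplit",
    "load_cell_table",
    "write_cell_table",
    "preprocess",
    "split_by_group",
    "tile_cells",
    "spatial_partition",
]

#: Columns that are never interpreted as gene expression.
RESERVED_COLUMNS = ("cell_id", "slice_id", "animal_id", "x", "y", "z", "cell_type")

GENE_ROLES = ("ligand", "receptor", "response", "control")
PARTITIONS = ("train", "validation", "test")


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ValidationError(ValueError):
    """Input values violate a domain invariant (e.g. negative expression)."""


class GeneRoleMap(Mapping):
    """Maps each gene name to a role in {ligand, receptor, response, control}.

    Ligands and receptors are predictors, responses are targets, controls are
    excluded from both.
    """

    def __init__(self, roles: Mapping[str, str]):
        roles = dict(roles)
        bad = {g: r for g, r in roles.items() if r not in GENE_ROLES}
        if bad:
            raise ValidationError(f"unknown gene roles: {bad}")
        self._roles = roles
        if not self.predictors:
            raise ValidationError("gene-role map has no ligand or receptor gene")
        if not self.responses:
            raise ValidationError("gene-role map has no response gene")

    def __getitem__(self, gene: str) -> str:
        return self._roles[gene]

    def __iter__(self):
        return iter(self._roles)

    def __len__(self) -> int:
        return len(self._roles)

    @property
    def predictors(self) -> list[str]:
        return [g for g, r in self._roles.items() if r in ("ligand", "receptor")]

    @property
    def responses(self) -> list[str]:
        return [g for g, r in self._roles.items() if r == "response"]

    @property
    def controls(self) -> list[str]:
        return [g for g, r in self._roles.items() if r == "control"]

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "GeneRoleMap":
        df = pd.read_csv(path, sep="\t")
        for col in ("gene", "role"):
            if col not in df.columns:
                raise SchemaError(f"gene-role map missing required column {col!r}")
        return cls(dict(zip(df["gene"].astype(str), df["role"].astype(str))))

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame({"gene": list(self._roles), "role": list(self._roles.values())}).to_csv(
            path, sep="\t", index=False
        )


class CellTable:
    """A validated per-cell table: coordinates, identifiers, and expression.

    Parameters
    ----------
    data:
        One row per cell. Required columns: ``cell_id``, ``slice_id``, ``x``,
        ``y``. Optional: ``z``, ``animal_id``, ``cell_type``. Every remaining
        column is treated as a gene unless ``genes`` is given explicitly.
    genes:
        Optional explicit list of gene columns.
    """

    def __init__(self, data: pd.DataFrame, genes: Iterable[str] | None = None):
        data = data.copy().reset_index(drop=True)
        for col in ("cell_id", "slice_id", "x", "y"):
            if col not in data.columns:
                raise SchemaError(f"cell table missing required column {col!r}")
        if genes is None:
            genes = [c for c in data.columns if c not in RESERVED_COLUMNS]
        else:
            genes = list(genes)
            missing = [g for g in genes if g not in data.columns]
            if missing:
                raise SchemaError(f"gene columns not in table: {missing}")

        data["cell_id"] = data["cell_id"].astype(str)
        data["slice_id"] = data["slice_id"].astype(str)

        coord_cols = ["x", "y"]
        if "z" in data.columns:
            z = data["z"].to_numpy(dtype=float)
            if np.isnan(z).all():
                data = data.drop(columns=["z"])
            elif np.isnan(z).any():
                raise ValidationError("mixed 2D/3D coordinates: some z values are missing")
            else:
                coord_cols.append("z")
        coords = data[coord_cols].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValidationError("non-finite cell coordinates")

        if genes:
            expr = data[genes].to_numpy(dtype=float)
            if not np.isfinite(expr).all():
                raise ValidationError("non-finite expression values")
            if (expr < 0).any():
                bad = [g for g in genes if (data[g].to_numpy(dtype=float) < 0).any()]
                raise ValidationError(f"negative expression values in columns {bad}")

        dup = data.duplicated(subset=["slice_id", "cell_id"])
        if dup.any():
            raise ValidationError("cell_id values are not unique within a slice")

        self.data = data
        self.genes = genes

    @property
    def is_3d(self) -> bool:
        return "z" in self.data.columns

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def has_cell_type(self) -> bool:
        return "cell_type" in self.data.columns

    def positions(self) -> np.ndarray:
        cols = ["x", "y", "z"] if self.is_3d else ["x", "y"]
        return self.data[cols].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "CellTable":
        return CellTable(self.data.loc[np.asarray(mask)], genes=self.genes)

    def __repr__(self) -> str:  # pragma: no cover
        dim = "3D" if self.is_3d else "2D"
        return f"CellTable({self.n_cells} cells, {len(self.genes)} genes, {dim})"


def load_cell_table(path: str | os.PathLike, format: str | None = None) -> CellTable:
    """Read a cell table from CSV/TSV or an AnnData ``.h5ad`` container.

    For ``.h5ad`` files, coordinates are read from ``obsm["spatial"]``,
    expression from ``X``, and identifiers from ``obs``.
    """
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "h5ad": "h5ad"}.get(ext, "csv")
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t")
        return CellTable(df)
    if format == "h5ad":
        import anndata

        ad = anndata.read_h5ad(path)
        if "spatial" not in ad.obsm:
            raise SchemaError("h5ad file has no obsm['spatial'] coordinates")
        coords = np.asarray(ad.obsm["spatial"], dtype=float)
        X = ad.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        df = pd.DataFrame(np.asarray(X, dtype=float), columns=list(ad.var_names))
        df.insert(0, "cell_id", list(ad.obs_names))
        if "slice_id" not in ad.obs.columns:
            raise SchemaError("h5ad file missing obs column 'slice_id'")
        df.insert(1, "slice_id", ad.obs["slice_id"].to_numpy())
        for opt in ("animal_id", "cell_type"):
            if opt in ad.obs.columns:
                df[opt] = ad.obs[opt].to_numpy()
        df["x"] = coords[:, 0]
        df["y"] = coords[:, 1]
        if coords.shape[1] > 2:
            df["z"] = coords[:, 2]
        return CellTable(df, genes=list(ad.var_names))
    raise ValueError(f"unknown cell-table format {format!r}")


def write_cell_table(cells: CellTable, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a cell table to CSV/TSV or ``.h5ad`` (inverse of :func:`load_cell_table`)."""
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "h5ad": "h5ad"}.get(ext, "csv")
    if format in ("csv", "tsv"):
        cells.data.to_csv(path, sep="," if format == "csv" else "\t", index=False)
        return
    if format == "h5ad":
        import anndata

        df = cells.data
        obs_cols = [c for c in ("slice_id", "animal_id", "cell_type") if c in df.columns]
        obs = df[obs_cols].copy()
        obs.index = df["cell_id"].astype(str)
        ad = anndata.AnnData(
            X=df[cells.genes].to_numpy(dtype=float),
            obs=obs,
            var=pd.DataFrame(index=cells.genes),
        )
        ad.obsm["spatial"] = cells.positions()
        ad.write_h5ad(path)
        return
    raise ValueError(f"unknown cell-table format {format!r}")


def preprocess(cells: CellTable, roles: GeneRoleMap) -> CellTable:
    """Apply the standard preprocessing: log1p on predictors, drop controls.

    Ligand and receptor columns are replaced by ``log(1 + value)``; response
    columns are left untransformed (they are the raw prediction targets);
    control genes are removed entirely.
    """
    unmapped = [g for g in cells.genes if g not in roles]
    if unmapped:
        raise SchemaError(f"expression columns missing from the gene-role map: {unmapped}")
    df = cells.data.copy()
    predictors = [g for g in cells.genes if roles[g] in ("ligand", "receptor")]
    controls = [g for g in cells.genes if roles[g] == "control"]
    for g in predictors:
        df[g] = np.log1p(df[g].to_numpy(dtype=float))
    df = df.drop(columns=controls)
    return CellTable(df, genes=[g for g in cells.genes if g not in controls])


@dataclass
class DataSplit:
    """Per-cell train/validation/test assignment.

    ``frame`` has columns ``cell_id``, ``slice_id``, ``partition`` and
    ``group``. The group column records the unit the split was made on (an
    animal, a slice, or a spatial tile); it is also the clustering unit for
    the paired bootstrap test downstream.
    """

    frame: pd.DataFrame
    mode: str  # "by_group" or "spatial"
    dropped_cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        bad = set(self.frame["partition"]) - set(PARTITIONS)
        if bad:
            raise ValidationError(f"unknown partition labels: {bad}")

    def partition_cells(self, partition: str) -> pd.DataFrame:
        return self.frame[self.frame["partition"] == partition]

    def counts(self) -> pd.Series:
        return self.frame["partition"].value_counts()

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.frame[["cell_id", "partition"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, cells: CellTable) -> "DataSplit":
        df = pd.read_csv(path, sep="\t")
        for col in ("cell_id", "partition"):
            if col not in df.columns:
                raise SchemaError(f"split file missing required column {col!r}")
        df["cell_id"] = df["cell_id"].astype(str)
        merged = df.merge(cells.data[["cell_id", "slice_id"]], on="cell_id", how="left")
        if merged["slice_id"].isna().any():
            raise ValidationError("split file references cells absent from the table")
        merged["group"] = merged["slice_id"]
        return cls(frame=merged[["cell_id", "slice_id", "partition", "group"]], mode="by_group")


def _allocate_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n units into three partitions, each >= 1."""
    fr = np.asarray(fractions, dtype=float)
    if (fr <= 0).any() or not np.isclose(fr.sum(), 1.0):
        raise ValidationError("fractions must be positive and sum to 1")
    ideal = fr * n
    counts = np.floor(ideal).astype(int)
    order = np.argsort(-(ideal - counts), kind="stable")
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    # Each partition must be non-empty.
    while (counts == 0).any():
        counts[np.argmax(counts == 0)] += 1
        counts[np.argmax(counts)] -= 1
    return counts.tolist()


def split_by_group(
    cells: CellTable,
    group_key: str,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DataSplit:
    """Split cells into train/validation/test by whole groups (e.g. animals).

    No group ever spans two partitions. Deterministic given ``seed``.
    """
    if group_key not in cells.data.columns:
        raise SchemaError(f"group column {group_key!r} not in cell table")
    groups = np.array(sorted(cells.data[group_key].astype(str).unique()))
    if len(groups) < 3:
        raise ValidationError(
            f"need at least 3 groups to form three partitions, got {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    groups = groups[rng.permutation(len(groups))]
    counts = _allocate_counts(len(groups), fractions)
    assignment: dict[str, str] = {}
    start = 0
    for part, cnt in zip(PARTITIONS, counts):
        for g in groups[start : start + cnt]:
            assignment[g] = part
        start += cnt
    frame = cells.data[["cell_id", "slice_id"]].copy()
    frame["group"] = cells.data[group_key].astype(str)
    frame["partition"] = frame["group"].map(assignment)
    return DataSplit(frame=frame[["cell_id", "slice_id", "partition", "group"]], mode="by_group")


def tile_cells(
    values: np.ndarray, n_parts: int, buffer: float
) -> tuple[np.ndarray, np.ndarray]:
    """Tile a 1-D coordinate into ``n_parts`` equal-count intervals with buffer strips.

    Returns ``(tile_index, keep_mask)``. Cells strictly within ``buffer / 2``
    of an internal tile boundary are marked dropped, so retained cells in
    different tiles are always more than ``buffer`` apart along this axis.
    """
    values = np.asarray(values, dtype=float)
    if n_parts < 2:
        raise ValidationError("tiling requires n_parts >= 2")
    if buffer < 0:
        raise ValidationError("buffer must be non-negative")
    qs = np.quantile(values, np.linspace(0, 1, n_parts + 1)[1:-1])
    tile = np.searchsorted(qs, values, side="right")
    keep = np.ones(len(values), dtype=bool)
    if buffer > 0:
        for b in qs:
            keep &= np.abs(values - b) >= buffer / 2.0
    return tile, keep


def spatial_partition(
    cells: CellTable,
    n_parts: int,
    buffer: float,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DataSplit:
    """Partition a tissue into spatially disconnected train/validation/test regions.

    Each slice is tiled along its longest coordinate axis into ``n_parts``
    equal-count tiles; cells within ``buffer / 2`` of an internal boundary are
    dropped, so no retained cell in one tile lies within ``buffer`` of a
    retained cell in another. Whole tiles are then assigned to partitions. Use
    ``buffer`` at least as large as the largest graph radius you intend to
    sweep, so the partitions share no edges or receptive fields.
    """
    if n_parts < 3:
        raise ValidationError("spatial partition requires n_parts >= 3")
    rng = np.random.default_rng(seed)
    frames = []
    dropped: list[str] = []
    for slice_id, sub in cells.data.groupby("slice_id", sort=True):
        pos = sub[["x", "y", "z"] if cells.is_3d else ["x", "y"]].to_numpy(dtype=float)
        axis = int(np.argmax(pos.max(axis=0) - pos.min(axis=0)))
        tile, keep = tile_cells(pos[:, axis], n_parts, buffer)
        if len(np.unique(tile[keep])) < n_parts:
            raise ValidationError(
                f"slice {slice_id!r}: tiling produced an empty tile; use fewer parts"
            )
        counts = _allocate_counts(n_parts, fractions)
        tiles = rng.permutation(n_parts)
        tile_part = {}
        start = 0
        for part, cnt in zip(PARTITIONS, counts):
            for t in tiles[start : start + cnt]:
                tile_part[int(t)] = part
            start += cnt
        f = pd.DataFrame(
            {
                "cell_id": sub["cell_id"].to_numpy(),
                "slice_id": slice_id,
                "partition": [tile_part[int(t)] for t in tile],
                "group": [f"{slice_id}/tile{t}" for t in tile],
            }
        )
        frames.append(f[keep])
        dropped.extend(sub["cell_id"].to_numpy()[~keep].tolist())
    frame = pd.concat(frames, ignore_index=True)
    return DataSplit(frame=frame, mode="spatial", dropped_cell_ids=dropped)
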