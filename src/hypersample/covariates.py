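"""Covariate stack data model: co-registered raster layers, sample designs,
point extraction, and point-table I/O.

The stack is the population from which every sampling design draws.  All
statistics downstream (quantiles, bin proportions, covariance) are computed
over the intersection of the per-layer valid masks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import raster
from .errors import (
    AlignmentError,
    EmptyStackError,
    GeographicCRSError,
    OutOfBoundsError,
)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class CovariateLayer:
    """One raster covariate.  Categorical layers hold integer codes (stored
    as floats with NaN for nodata); ``categories`` lists the codes present."""

    name: str
    kind: str
    values: np.ndarray
    units: str = ""
    categories: tuple = ()

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"layer {self.name!r}: kind must be continuous or categorical")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: expected a 2-D grid")
        if self.kind == CATEGORICAL and not self.categories:
            valid = self.values[np.isfinite(self.values)]
            self.categories = tuple(sorted(np.unique(valid).astype(int)))


@dataclass
class CovariateStack:
    """Ordered, co-registered covariate layers plus shared grid geometry.

    ``mask`` is True where every layer is valid; ``r`` counts those cells.
    """

    layers: list[CovariateLayer]
    transform: raster.GridTransform
    crs: str | None = None
    mask: np.ndarray = field(init=False)
    r: int = field(init=False)

    def __post_init__(self):
        if not self.layers:
            raise EmptyStackError("stack has no layers")
        shape = self.layers[0].values.shape
        for layer in self.layers:
            if layer.values.shape != shape:
                raise AlignmentError(
                    f"layer {layer.name!r} has shape {layer.values.shape}, expected {shape}"
                )
        if raster.crs_is_geographic(self.crs):
            raise GeographicCRSError(
                f"CRS {self.crs!r} is geographic; a projected, meter-unit CRS is required"
            )
        self.mask = np.all([np.isfinite(l.values) for l in self.layers], axis=0)
        self.r = int(self.mask.sum())
        if self.r == 0:
            raise EmptyStackError("no cell is valid in every layer")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].values.shape

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    @property
    def continuous_names(self) -> list[str]:
        return [l.name for l in self.layers if l.kind == CONTINUOUS]

    @property
    def categorical_names(self) -> list[str]:
        return [l.name for l in self.layers if l.kind == CATEGORICAL]

    def __getitem__(self, name: str) -> CovariateLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def valid_cells(self) -> np.ndarray:
        """(r, 2) array of (row, col) indices of valid cells, row-major order."""
        rows, cols = np.nonzero(self.mask)
        return np.column_stack([rows, cols])

    def cell_centers(self, cells: np.ndarray):
        cells = np.atleast_2d(np.asarray(cells, dtype=int))
        return self.transform.cell_center(cells[:, 0], cells[:, 1])

    def locate(self, x, y) -> np.ndarray:
        """(row, col) of the cells containing the given coordinates."""
        row, col = self.transform.locate(x, y)
        nrow, ncol = self.shape
        bad = (row < 0) | (row >= nrow) | (col < 0) | (col >= ncol)
        if np.any(bad):
            idx = np.nonzero(np.atleast_1d(bad))[0]
            raise OutOfBoundsError(f"points outside raster extent: ids {idx.tolist()}")
        return np.column_stack([np.atleast_1d(row), np.atleast_1d(col)])

    # -- value access -----------------------------------------------------
    def table(self, cells: np.ndarray | None = None) -> pd.DataFrame:
        """Covariate values as a DataFrame, one row per cell.

        With ``cells=None`` returns the whole valid population (row-major)."""
        if cells is None:
            cells = self.valid_cells()
        cells = np.atleast_2d(np.asarray(cells, dtype=int))
        data = {l.name: l.values[cells[:, 0], cells[:, 1]] for l in self.layers}
        return pd.DataFrame(data)

    def continuous_matrix(self, cells: np.ndarray | None = None) -> np.ndarray:
        """(m, k_cont) matrix of continuous covariate values."""
        if cells is None:
            cells = self.valid_cells()
        cells = np.atleast_2d(np.asarray(cells, dtype=int))
        cols = [self[n].values[cells[:, 0], cells[:, 1]] for n in self.continuous_names]
        return np.column_stack(cols) if cols else np.empty((len(cells), 0))

    def population_correlation(self) -> np.ndarray:
        """Pearson correlation of continuous covariates over valid cells."""
        mat = self.continuous_matrix()
        if mat.shape[1] < 2:
            return np.ones((mat.shape[1], mat.shape[1]))
        return np.corrcoef(mat, rowvar=False)


@dataclass
class SampleDesign:
    """A set of sampled cells with provenance and their covariate values."""

    cells: np.ndarray  # (n, 2) int (row, col)
    x: np.ndarray
    y: np.ndarray
    provenance: list[str]
    table: pd.DataFrame
    ids: list | None = None

    def __post_init__(self):
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=int))

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n(self) -> int:
        return len(self.cells)

    @classmethod
    def from_cells(cls, stack: CovariateStack, cells, provenance="clhs", ids=None) -> "SampleDesign":
        cells = np.atleast_2d(np.asarray(cells, dtype=int))
        on_mask = stack.mask[cells[:, 0], cells[:, 1]]
        if not np.all(on_mask):
            bad = np.nonzero(~on_mask)[0]
            raise OutOfBoundsError(f"cells off the valid mask: ids {bad.tolist()}")
        x, y = stack.cell_centers(cells)
        prov = [provenance] * len(cells) if isinstance(provenance, str) else list(provenance)
        return cls(cells=cells, x=x, y=y, provenance=prov, table=stack.table(cells), ids=ids)


# ---------------------------------------------------------------------------
# readers / writers


def read_stack(paths, kinds, names=None, crs=None) -> CovariateStack:
    """Read single-band rasters into a co-registered stack.

    Raises :class:`AlignmentError` naming the first offending layer on any
    shape or transform mismatch.
    """
    paths = list(paths)
    kinds = list(kinds)
    if len(kinds) != len(paths):
        raise ValueError("one kind flag per raster path is required")
    if names is None:
        names = [Path(p).stem for p in paths]
    layers = []
    ref_transform = None
    ref_shape = None
    for path, kind, name in zip(paths, kinds, names):
        values, transform = raster.read_raster(path)
        if ref_transform is None:
            ref_transform, ref_shape = transform, values.shape
        else:
            if values.shape != ref_shape:
                raise AlignmentError(
                    f"layer {name!r} ({path}): shape {values.shape} != {ref_shape}"
                )
            if not transform.close_to(ref_transform):
                raise AlignmentError(f"layer {name!r} ({path}): transform mismatch")
        layers.append(CovariateLayer(name=name, kind=kind, values=values))
    return CovariateStack(layers=layers, transform=ref_transform, crs=crs)


def read_manifest(path) -> CovariateStack:
    """Read a YAML manifest listing layer path/name/kind (paths relative to
    the manifest file)."""
    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    entries = spec["layers"]
    paths = [path.parent / e["path"] for e in entries]
    kinds = [e.get("kind", CONTINUOUS) for e in entries]
    names = [e.get("name", Path(e["path"]).stem) for e in entries]
    return read_stack(paths, kinds, names=names, crs=spec.get("crs"))


def write_manifest(path, entries, crs=None) -> None:
    doc = {"layers": entries}
    if crs is not None:
        doc["crs"] = crs
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def extract_table(stack: CovariateStack, points=None, cells=None, ids=None,
                  provenance="extracted") -> SampleDesign:
    """Build a :class:`SampleDesign` from coordinates or cell indices.

    Points landing on nodata cells are reported via a warning and excluded
    from the covariate table.  Points outside the extent raise
    :class:`OutOfBoundsError` carrying their ids.
    """
    if (points is None) == (cells is None):
        raise ValueError("provide exactly one of points= or cells=")
    if points is not None:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if ids is None:
            ids = list(range(len(points)))
        cells = stack.locate(points[:, 0], points[:, 1])
    else:
        cells = np.atleast_2d(np.asarray(cells, dtype=int))
        if ids is None:
            ids = list(range(len(cells)))
    on_mask = stack.mask[cells[:, 0], cells[:, 1]]
    if not np.all(on_mask):
        dropped = [ids[i] for i in np.nonzero(~on_mask)[0]]
        warnings.warn(f"points on nodata cells excluded: ids {dropped}", UserWarning)
        cells = cells[on_mask]
        ids = [ids[i] for i in np.nonzero(on_mask)[0]]
    if len(cells) == 0:
        raise EmptyStackError("all points fell on nodata cells")
    return SampleDesign.from_cells(stack, cells, provenance=provenance, ids=ids)


def write_points(design: SampleDesign, path, format: str = "csv") -> None:
    """Write a design as CSV or GeoJSON; raises before creating the file if
    the design is empty."""
    if design.n == 0:
        raise ValueError("refusing to write an empty design")
    df = pd.DataFrame({"x": design.x, "y": design.y, "provenance": design.provenance})
    if design.ids is not None:
        df.insert(0, "id", design.ids)
    for col in design.table.columns:
        df[col] = design.table[col].to_numpy()
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "geojson":
        features = []
        for _, row in df.iterrows():
            props = {k: (v.item() if isinstance(v, np.generic) else v)
                     for k, v in row.items() if k not in ("x", "y")}
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                "properties": props,
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_points(path) -> pd.DataFrame:
    """Read a point table (CSV with x,y columns or GeoJSON point features)."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            doc = json.load(fh)
        rows = []
        for feat in doc["features"]:
            cx, cy = feat["geometry"]["coordinates"][:2]
            rows.append({"x": cx, "y": cy, **feat.get("properties", {})})
        return pd.DataFrame(rows)
    return pd.read_csv(path)
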