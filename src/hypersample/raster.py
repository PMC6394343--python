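"""Single-band raster I/O (GeoTIFF and ESRI ASCII grid) and grid geometry.

Only north-up, square-ish pixel grids in a projected (meter-unit) CRS are
supported.  GeoTIFF georeferencing is carried by the ModelPixelScale /
ModelTiepoint / GeoKeyDirectory tags; ESRI ``.asc`` grids carry it in their
text header.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import GeographicCRSError

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_MODEL_PROJECTED = 1
_MODEL_GEOGRAPHIC = 2
_KEY_PROJECTED_CS = 3072

# EPSG codes of common geographic CRSs; used for the manifest-level check when
# no GeoTIFF keys are available.  pyproj is deliberately not a dependency.
_GEOGRAPHIC_EPSG = {4326, 4269, 4283, 4258, 4267, 4759, 4148}


@dataclass(frozen=True)
class GridTransform:
    """North-up affine grid geometry.

    ``x0, y0`` is the outer corner of the top-left cell; ``dx, dy`` are the
    positive cell width/height in CRS units (meters).  Row 0 is the top row.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def cell_center(self, rows, cols):
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.x0 + (cols + 0.5) * self.dx
        y = self.y0 - (rows + 0.5) * self.dy
        return x, y

    def locate(self, x, y):
        """Map coordinates to (row, col).  Cells are half-open: a point on a
        shared edge belongs to the cell to its right/below."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - y) / self.dy).astype(int)
        return row, col

    def close_to(self, other: "GridTransform", tol: float = 1e-6) -> bool:
        return (
            math.isclose(self.x0, other.x0, abs_tol=tol)
            and math.isclose(self.y0, other.y0, abs_tol=tol)
            and math.isclose(self.dx, other.dx, abs_tol=tol)
            and math.isclose(self.dy, other.dy, abs_tol=tol)
        )


def crs_is_geographic(crs: str | int | None) -> bool:
    """Heuristic geographic-CRS detection for manifest-supplied CRS strings."""
    if crs is None:
        return False
    if isinstance(crs, int):
        return crs in _GEOGRAPHIC_EPSG
    text = str(crs).strip().lower()
    m = re.match(r"epsg:\s*(\d+)", text)
    if m:
        return int(m.group(1)) in _GEOGRAPHIC_EPSG
    return any(token in text for token in ("longlat", "wgs 84", "wgs84", "latitude", "geographic"))


def _epsg_from_crs(crs: str | int | None) -> int | None:
    if crs is None:
        return None
    if isinstance(crs, int):
        return crs
    m = re.match(r"epsg:\s*(\d+)", str(crs).strip().lower())
    return int(m.group(1)) if m else None


def write_geotiff(path, values: np.ndarray, transform: GridTransform, crs=None) -> None:
    """Write a single-band float GeoTIFF; nodata is encoded as NaN."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("only single-band 2-D rasters are supported")
    keys = [_KEY_MODEL_TYPE, 0, 1, _MODEL_PROJECTED]
    epsg = _epsg_from_crs(crs)
    if epsg is not None:
        keys += [_KEY_PROJECTED_CS, 0, 1, epsg]
    nkeys = len(keys) // 4
    geokeys = [1, 1, 0, nkeys] + keys
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.dx, transform.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), tuple(geokeys)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, arr, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GridTransform]:
    """Read a single-band GeoTIFF written with metric georeferencing.

    Raises :class:`GeographicCRSError` if the file declares a geographic
    model type (degree units).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = np.asarray(page.asarray(), dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        tags = page.tags
        geokeys = tags.get(_TAG_GEOKEYS)
        if geokeys is not None:
            vals = list(geokeys.value)
            for i in range(4, len(vals), 4):
                if vals[i] == _KEY_MODEL_TYPE and vals[i + 3] == _MODEL_GEOGRAPHIC:
                    raise GeographicCRSError(
                        f"{path}: geographic CRS detected; a projected, meter-unit CRS is required"
                    )
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        if scale is None or tie is None:
            # ungeoreferenced TIFF: unit cells anchored at the origin
            transform = GridTransform(0.0, float(arr.shape[0]), 1.0, 1.0)
        else:
            dx, dy = float(scale.value[0]), float(scale.value[1])
            x0, y0 = float(tie.value[3]), float(tie.value[4])
            transform = GridTransform(x0, y0, dx, dy)
        nodata = tags.get(_TAG_GDAL_NODATA)
        if nodata is not None:
            text = str(nodata.value).strip().strip("\x00")
            if text.lower() not in ("nan", ""):
                arr[arr == float(text)] = np.nan
    return arr, transform


def write_asc(path, values: np.ndarray, transform: GridTransform, nodata=-9999.0) -> None:
    """Write an ESRI ASCII grid (plain text, square cells only)."""
    arr = np.asarray(values, dtype=np.float64)
    if not math.isclose(transform.dx, transform.dy, rel_tol=1e-9):
        raise ValueError("ESRI ASCII grids require square cells")
    nrows, ncols = arr.shape
    out = arr.copy()
    out[np.isnan(out)] = nodata
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {transform.x0!r}\n"
        f"yllcorner {transform.y0 - nrows * transform.dy!r}\n"
        f"cellsize {transform.dx!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_asc(path) -> tuple[np.ndarray, GridTransform]:
    header = {}
    with open(path) as fh:
        pos = 0
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        arr = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if arr.shape != (nrows, ncols):
        raise ValueError(f"{path}: grid shape {arr.shape} disagrees with header")
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    arr[arr == nodata] = np.nan
    transform = GridTransform(header["xllcorner"], header["yllcorner"] + nrows * cell, cell, cell)
    return arr, transform


def read_raster(path) -> tuple[np.ndarray, GridTransform]:
    """Dispatch on file extension (.tif/.tiff vs .asc/.agr/.grd)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return read_geotiff(path)
    if suffix in (".asc", ".agr", ".grd", ".txt"):
        return read_asc(path)
    raise ValueError(f"unrecognized raster format: {path}")


def write_raster(path, values, transform, crs=None) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        write_geotiff(path, values, transform, crs=crs)
    elif suffix in (".asc", ".agr", ".grd", ".txt"):
        write_asc(path, values, transform)
    else:
        raise ValueError(f"unrecognized raster format: {path}")
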