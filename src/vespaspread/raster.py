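"""Georeferenced raster grids and raster stacks.

All grids live on a plain WGS84 lon/lat lattice indexed row-major from the
top-left corner with square pixels.  Point-to-cell mapping uses half-open
cell intervals ``[edge, edge + pixel)`` along both axes, so extraction is
deterministic on cell boundaries.  Two on-disk formats are supported: ESRI
ASCII grid (``.asc``) and single-band GeoTIFF (``.tif``/``.tiff``) carrying
the standard ModelPixelScale/ModelTiepoint/GDAL_NODATA tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RasterGrid",
    "EnvStack",
    "read_raster",
    "write_raster",
    "extract_values",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory declaring WGS84 geographic, pixel-is-area.
_WGS84_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass
class RasterGrid:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values
        2-D array, row 0 at the northern edge.
    origin_lon, origin_lat
        Decimal degrees of the grid's top-left *corner* (not cell center).
    pixel_size
        Degrees per pixel; pixels are square.
    nodata
        Sentinel marking missing cells.
    name
        Free-text label (layer name).
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    pixel_size: float
    nodata: float = -9999.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster values must be a 2-D lattice of at least 1x1")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        lon_max = self.origin_lon + self.ncols * self.pixel_size
        lat_min = self.origin_lat - self.nrows * self.pixel_size
        if not (-180.0 - 1e-9 <= self.origin_lon and lon_max <= 180.0 + 1e-9):
            raise ValueError("longitude extent outside [-180, 180]")
        if not (-90.0 - 1e-9 <= lat_min and self.origin_lat <= 90.0 + 1e-9):
            raise ValueError("latitude extent outside [-90, 90]")
        vals = self.values
        if np.issubdtype(vals.dtype, np.floating):
            bad = ~np.isfinite(vals) & ~np.isnan(vals)
            if bad.any():
                raise ValueError("non-finite, non-nodata values in raster")
            # NaN is tolerated only as an alias for nodata
            self.values = np.where(np.isnan(vals), self.nodata, vals)

    # -- lattice geometry -------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geotransform(self) -> tuple[float, float, float]:
        return (self.origin_lon, self.origin_lat, self.pixel_size)

    def same_lattice(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            self.geotransform(), other.geotransform(), atol=tol
        )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Lon/lat of cell centers for (arrays of) row/col indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.pixel_size
        lat = self.origin_lat - (row + 0.5) * self.pixel_size
        return lon, lat

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map lon/lat to (row, col) using half-open cell intervals.

        Returned indices may fall outside the lattice; callers check bounds.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.pixel_size + 1e-12).astype(int)
        row = np.floor((self.origin_lat - lat) / self.pixel_size + 1e-12).astype(int)
        return row, col

    def in_bounds(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    # -- masks ------------------------------------------------------------

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    @property
    def data_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        """A new grid on the same lattice holding *values*."""
        return replace(
            self, values=np.asarray(values), name=self.name if name is None else name
        )

    def equals(self, other: "RasterGrid", atol: float = 0.0) -> bool:
        if not self.same_lattice(other):
            return False
        if atol == 0.0:
            return bool(np.array_equal(self.values, other.values))
        return bool(np.allclose(self.values, other.values, atol=atol))


@dataclass
class EnvStack:
    """Named, ordered collection of co-registered :class:`RasterGrid` layers."""

    layers: list[RasterGrid] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [g.name for g in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        if self.layers:
            tmpl = self.layers[0]
            for g in self.layers[1:]:
                if not g.same_lattice(tmpl):
                    raise ValueError(
                        f"layer {g.name!r} not co-registered with {tmpl.name!r}: "
                        f"shape {g.shape} vs {tmpl.shape}, "
                        f"geotransform {g.geotransform()} vs {tmpl.geotransform()}"
                    )

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        for g in self.layers:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.layers]

    @property
    def template(self) -> RasterGrid:
        if not self.layers:
            raise ValueError("empty stack")
        return self.layers[0]

    def array(self) -> np.ndarray:
        """(n_layers, nrows, ncols) stacked values."""
        return np.stack([g.values for g in self.layers])

    def table(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (n_cells, n_layers) plus a per-cell validity mask."""
        arr = self.array().reshape(len(self), -1).T
        valid = np.ones(arr.shape[0], dtype=bool)
        for k, g in enumerate(self.layers):
            valid &= arr[:, k] != g.nodata
        return arr, valid


# ---------------------------------------------------------------------------
# I/O


def _write_ascii(grid: RasterGrid, path: Path) -> None:
    vals = grid.values
    is_int = np.issubdtype(vals.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_lon:.12g}\n")
        fh.write(f"yllcorner {grid.origin_lat - grid.nrows * grid.pixel_size:.12g}\n")
        fh.write(f"cellsize {grid.pixel_size:.12g}\n")
        fh.write(f"NODATA_value {grid.nodata:.12g}\n")
        fmt = "%d" if is_int else "%.10g"
        np.savetxt(fh, vals, fmt=fmt)


def _read_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    nrows = int(header["nrows"])
    if vals.shape != (nrows, int(header["ncols"])):
        raise ValueError(f"ASCII grid {path}: data shape {vals.shape} != header")
    px = header["cellsize"]
    if vals.size and np.all(vals == np.floor(vals)) and np.abs(vals).max() < 2**53:
        as_int = vals.astype(np.int64)
        if np.array_equal(as_int.astype(float), vals):
            vals = as_int
    return RasterGrid(
        values=vals,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + nrows * px,
        pixel_size=px,
        nodata=nodata,
        name=path.stem,
    )


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    vals = grid.values
    if np.issubdtype(vals.dtype, np.floating):
        vals = vals.astype(np.float64)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0), False),
        (
            _MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0),
            False,
        ),
        (_GEO_KEY_DIRECTORY, "H", len(_WGS84_KEYS), _WGS84_KEYS, False),
        (_GDAL_NODATA, "s", 0, f"{grid.nodata:.12g}", False),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def _read_geotiff(path: Path) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray()
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: not a GeoTIFF (missing geo tags)")
        sx, sy = tags[_MODEL_PIXEL_SCALE].value[:2]
        if not np.isclose(sx, sy):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy}) unsupported")
        tie = tags[_MODEL_TIEPOINT].value
        nodata = -9999.0
        if _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)
    return RasterGrid(
        values=vals,
        origin_lon=float(tie[3]),
        origin_lat=float(tie[4]),
        pixel_size=float(sx),
        nodata=nodata,
        name=path.stem,
    )


def read_raster(path: str | Path) -> RasterGrid:
    """Read a GeoTIFF or ESRI ASCII grid from *path* (dispatch on suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path)
    return _read_ascii(path)


def write_raster(grid: RasterGrid, path: str | Path, format: str | None = None) -> None:
    """Write *grid* to *path* as ``"ascii"`` or ``"geotiff"``.

    With ``format=None`` the format follows the file suffix.  Written files
    round-trip through :func:`read_raster` bit-exactly for integer grids and
    to float64 precision for float grids.
    """
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii"
    if format == "geotiff":
        _write_geotiff(grid, path)
    elif format == "ascii":
        _write_ascii(grid, path)
    else:
        raise ValueError(f"unknown raster format {format!r}")


# ---------------------------------------------------------------------------
# Point extraction


def extract_values(stack: EnvStack, occ) -> pd.DataFrame:
    """Sample every stack layer at each occurrence point.

    Returns a DataFrame with ``lon``/``lat``, one column per layer, and two
    flag columns: ``outside`` (point off the lattice) and ``nodata`` (any
    required layer missing there).  Flagged rows are retained, never silently
    dropped; ``df.attrs["n_flagged"]`` carries the total count.
    """
    tmpl = stack.template
    pts = np.asarray(occ.points, dtype=float)
    row, col = tmpl.index_of(pts[:, 0], pts[:, 1])
    inside = tmpl.in_bounds(row, col)
    out = pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1]})
    r = np.where(inside, row, 0)
    c = np.where(inside, col, 0)
    any_nodata = np.zeros(len(pts), dtype=bool)
    for g in stack.layers:
        v = g.values[r, c].astype(float)
        hit_nodata = v == g.nodata
        any_nodata |= hit_nodata
        v[~inside | hit_nodata] = np.nan
        out[g.name] = v
    out["outside"] = ~inside
    out["nodata"] = any_nodata & inside
    out.attrs["n_flagged"] = int((~inside).sum() + (any_nodata & inside).sum())
    return out
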