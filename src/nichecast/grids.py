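"""Raster and occurrence-table I/O on a shared analysis grid.

Everything downstream (thinning, feature extraction, prediction, projection)
assumes a single aligned grid: row 0 is the northernmost row, cell membership
uses half-open intervals ``[edge, edge + cell_size)``, and a cell that is
nodata in *any* environmental band is nodata everywhere.

The plain-text ESRI ASCII grid (``.asc``) is the primary interchange format;
single-band TIFF rasters (with an ESRI world file carrying the geometry) are
supported through :mod:`tifffile`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class AlignmentError(ValueError):
    """Raised when raster inputs do not share one grid geometry."""


class InputError(ValueError):
    """Raised on malformed or contract-violating inputs."""


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a north-up regular grid.

    ``(x_origin, y_origin)`` is the map coordinate of the north-west corner
    of the north-west cell; ``cell_size`` is in the grid's map units
    (degrees or metres).
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs_label: str = "unspecified"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InputError("grid must have at least one cell")
        if not self.cell_size > 0:
            raise InputError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a point to its (row, col), or None if off-grid.

        West/north edges belong to the cell (half-open convention); the
        grid's outer east/south edges are therefore exclusive.
        """
        col = math.floor((lon - self.x_origin) / self.cell_size)
        row = math.floor((self.y_origin - lat) / self.cell_size)
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return (x, y)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y[:, None], self.shape).copy()

    def matches(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class EnvGrid:
    """A stack of aligned environmental bands with one shared nodata mask."""

    geometry: GridGeometry
    band_names: list[str]
    values: np.ndarray  # (n_bands, n_rows, n_cols) float64
    nodata_mask: np.ndarray  # (n_rows, n_cols) bool, True = nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if len(self.band_names) != len(set(self.band_names)):
            raise InputError("duplicate band names")
        if self.values.shape != (len(self.band_names), *self.geometry.shape):
            raise InputError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.band_names)} bands on {self.geometry.shape}"
            )
        if self.nodata_mask.shape != self.geometry.shape:
            raise InputError("nodata mask shape mismatch")
        valid = self.values[:, ~self.nodata_mask]
        if valid.size and not np.all(np.isfinite(valid)):
            raise InputError("non-finite values on non-nodata cells")

    @property
    def n_bands(self) -> int:
        return len(self.band_names)

    def band(self, name: str) -> np.ndarray:
        try:
            return self.values[self.band_names.index(name)]
        except ValueError:
            raise InputError(f"unknown band {name!r}") from None

    def valid_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) indices of non-nodata cells."""
        return np.argwhere(~self.nodata_mask)

    def table_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Per-band values at the given cells, as a DataFrame."""
        return pd.DataFrame(
            {name: self.values[b, rows, cols] for b, name in enumerate(self.band_names)}
        )

    def subset(self, band_names: Sequence[str]) -> "EnvGrid":
        idx = [self.band_names.index(n) if n in self.band_names else -1 for n in band_names]
        if -1 in idx:
            raise InputError(f"unknown band {band_names[idx.index(-1)]!r}")
        return EnvGrid(self.geometry, list(band_names), self.values[idx].copy(),
                       self.nodata_mask.copy())

    def copy(self) -> "EnvGrid":
        return EnvGrid(self.geometry, list(self.band_names), self.values.copy(),
                       self.nodata_mask.copy())


@dataclass(frozen=True)
class OccurrenceRecord:
    lon: float
    lat: float
    source_tag: str = "unknown"
    cell: tuple[int, int] | None = None
    off_grid: bool = False


@dataclass
class OccurrenceSet:
    """Presence records; cell indices are attached by :func:`locate_cells`."""

    records: list[OccurrenceRecord] = field(default_factory=list)
    n_dropped_on_read: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def coords(self) -> np.ndarray:
        return np.array([[r.lon, r.lat] for r in self.records], dtype=float).reshape(-1, 2)

    def cells(self) -> np.ndarray:
        """(k, 2) rows/cols of located, on-grid records."""
        return np.array(
            [r.cell for r in self.records if r.cell is not None], dtype=int
        ).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lon": [r.lon for r in self.records],
                "lat": [r.lat for r in self.records],
                "source_tag": [r.source_tag for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

_ASCII_NODATA = -9999.0


def write_ascii_grid(path: Path | str, geometry: GridGeometry, band: np.ndarray,
                     mask: np.ndarray, nodata_value: float = _ASCII_NODATA) -> None:
    path = Path(path)
    data = np.where(mask, nodata_value, band)
    yll = geometry.y_origin - geometry.n_rows * geometry.cell_size
    lines = [
        f"ncols {geometry.n_cols}",
        f"nrows {geometry.n_rows}",
        f"xllcorner {geometry.x_origin!r}",
        f"yllcorner {yll!r}",
        f"cellsize {geometry.cell_size!r}",
        f"NODATA_value {nodata_value!r}",
    ]
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in data)
    path.write_text("\n".join(lines) + "\n" + body + "\n", encoding="utf-8")


def read_ascii_grid(path: Path | str) -> tuple[GridGeometry, np.ndarray, np.ndarray]:
    """Read one .asc file -> (geometry, values, nodata_mask)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open(encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, dtype=float)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise InputError(f"{path}: missing ASCII grid header field {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    body = np.asarray(body, dtype=float).reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", _ASCII_NODATA)
    mask = body == nodata
    geometry = GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
    )
    values = np.where(mask, np.nan, body)
    return geometry, values, mask


# ---------------------------------------------------------------------------
# TIFF (+ ESRI world file)
# ---------------------------------------------------------------------------

def _world_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + "w") if path.suffix.lower() not in {".tif", ".tiff"} \
        else path.with_suffix(".tfw")


def write_tiff_grid(path: Path | str, geometry: GridGeometry, band: np.ndarray,
                    mask: np.ndarray) -> None:
    import tifffile

    path = Path(path)
    data = np.where(mask, np.nan, band).astype(np.float32)
    tifffile.imwrite(path, data)
    cs = geometry.cell_size
    world = [cs, 0.0, 0.0, -cs,
             geometry.x_origin + cs / 2.0, geometry.y_origin - cs / 2.0]
    _world_path(path).write_text("\n".join(f"{v!r}" for v in world) + "\n", encoding="utf-8")


def read_tiff_grid(path: Path | str) -> tuple[GridGeometry, np.ndarray, np.ndarray]:
    import tifffile

    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim != 2:
        raise InputError(f"{path}: expected a single-band raster")
    wf = _world_path(path)
    if not wf.exists():
        raise InputError(f"{path}: missing world file {wf.name} with grid geometry")
    vals = [float(v) for v in wf.read_text().split()]
    cs = vals[0]
    geometry = GridGeometry(
        n_rows=data.shape[0], n_cols=data.shape[1],
        x_origin=vals[4] - cs / 2.0, y_origin=vals[5] + cs / 2.0, cell_size=cs,
    )
    mask = ~np.isfinite(data)
    return geometry, data, mask


def _read_band_file(path: Path) -> tuple[GridGeometry, np.ndarray, np.ndarray]:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return read_tiff_grid(path)
    return read_ascii_grid(path)


# ---------------------------------------------------------------------------
# Module operations
# ---------------------------------------------------------------------------

def read_env_grid(paths: Sequence[Path | str], band_names: Sequence[str] | None = None,
                  geometry_tol: float = 1e-9) -> EnvGrid:
    """Read one file per band into an aligned stack with a union nodata mask."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise InputError("no raster files given")
    if band_names is None:
        band_names = [p.stem for p in paths]
    if len(band_names) != len(paths):
        raise InputError("band_names length must match number of files")
    geometry: GridGeometry | None = None
    bands, masks = [], []
    for path in paths:
        geo, vals, mask = _read_band_file(path)
        if geometry is None:
            geometry = geo
        elif not geo.matches(geometry, geometry_tol):
            raise AlignmentError(f"{path}: geometry does not match {paths[0]}")
        bands.append(vals)
        masks.append(mask)
    union_mask = np.logical_or.reduce(masks)
    values = np.stack(bands)
    values[:, union_mask] = np.nan
    values = np.nan_to_num(values, nan=0.0)
    values[:, union_mask] = 0.0
    return EnvGrid(geometry, list(band_names), values, union_mask)


def write_env_grid(grid: EnvGrid, directory: Path | str, format: str = "ascii_grid") -> list[Path]:
    """Write one file per band; returns the written paths."""
    if grid.n_bands == 0:
        raise InputError("empty band list")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for b, name in enumerate(grid.band_names):
        if format == "ascii_grid":
            path = directory / f"{name}.asc"
            write_ascii_grid(path, grid.geometry, grid.values[b], grid.nodata_mask)
        elif format == "geotiff":
            path = directory / f"{name}.tif"
            write_tiff_grid(path, grid.geometry, grid.values[b], grid.nodata_mask)
        else:
            raise InputError(f"unknown raster format {format!r}")
        paths.append(path)
    return paths


def read_occurrences(csv_path: Path | str, lon_col: str = "lon",
                     lat_col: str = "lat", source_col: str | None = None) -> OccurrenceSet:
    """Read presence records from CSV, dropping unparseable/out-of-range rows.

    The number of dropped rows is recorded on the returned set
    (``n_dropped_on_read``); duplicates are retained here — deduplication is
    a separate, reported cleaning step.
    """
    df = pd.read_csv(csv_path)
    for col in (lon_col, lat_col):
        if col not in df.columns:
            raise InputError(f"{csv_path}: missing column {col!r}")
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    ok = lon.between(-180.0, 180.0) & lat.between(-90.0, 90.0) & lon.notna() & lat.notna()
    tags = df[source_col].astype(str) if source_col and source_col in df.columns \
        else pd.Series([Path(csv_path).name] * len(df))
    records = [
        OccurrenceRecord(float(lo), float(la), tag or "unknown")
        for lo, la, tag in zip(lon[ok], lat[ok], tags[ok])
    ]
    return OccurrenceSet(records, n_dropped_on_read=int((~ok).sum()))


def locate_cells(occ: OccurrenceSet, geometry: GridGeometry) -> OccurrenceSet:
    """Annotate each record with its (row, col), or flag it off-grid."""
    out = []
    for r in occ.records:
        cell = geometry.cell_of(r.lon, r.lat)
        out.append(replace(r, cell=cell, off_grid=cell is None))
    return OccurrenceSet(out, occ.n_dropped_on_read)
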