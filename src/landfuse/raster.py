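"""Raster containers and I/O for categorical grids and metric surfaces.

Two on-disk formats are supported: ESRI ASCII grid (plain text, the exchange
format every GIS reads) and single-band TIFF written through :mod:`tifffile`,
with the geotransform, nodata sentinel and CRS tag carried in a JSON
ImageDescription tag.  Interior arrays are row-major with cell (0, 0) at the
raster's top-left; all window geometry downstream is computed in cell units,
so cells must be square.

No reprojection or resampling: the two grades of a land-cover pair must be
delivered co-registered, and :func:`pair_rasters` enforces that plus the
vertical-consistency contract (the fine-grade class at every cell maps to the
coarse-grade class recorded there).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import (
    GridAlignmentError,
    RasterFormatError,
    VerticalConsistencyError,
)
from .hierarchy import ClassHierarchy, parent_of

__all__ = [
    "GridTransform",
    "Grid",
    "CategoricalRasterPair",
    "read_categorical",
    "read_grid",
    "write_grid",
    "write_surface",
    "pair_rasters",
]

DEFAULT_NODATA = -9999


@dataclass(frozen=True)
class GridTransform:
    """Origin (lower-left corner, map units) and square cell size."""

    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        if not self.cellsize > 0:
            raise ValueError(f"cell size must be positive, got {self.cellsize}")

    def close_to(self, other: "GridTransform", rtol: float = 1e-9) -> bool:
        return (
            np.isclose(self.xllcorner, other.xllcorner, rtol=rtol, atol=1e-9)
            and np.isclose(self.yllcorner, other.yllcorner, rtol=rtol, atol=1e-9)
            and np.isclose(self.cellsize, other.cellsize, rtol=rtol)
        )


@dataclass
class Grid:
    """A rectangular single-band raster.

    ``values`` holds integer class codes (categorical) or float metric values
    (surfaces); ``nodata`` is the sentinel marking cells outside the valid
    area and must never collide with a real class code.
    """

    values: np.ndarray
    nodata: float = DEFAULT_NODATA
    transform: GridTransform = GridTransform()
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        if np.issubdtype(self.values.dtype, np.floating):
            return ~(np.isnan(self.values) | (self.values == self.nodata))
        return self.values != self.nodata

    def masked_values(self) -> np.ndarray:
        """Valid cell values as a flat array."""
        return self.values[self.valid_mask]

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.nodata, self.transform, self.crs_tag)


@dataclass
class CategoricalRasterPair:
    """Co-registered coarse-grade (g1) and fine-grade (g2) class rasters.

    Invariant: on every valid cell the hierarchy maps ``g2`` to ``g1``
    (vertical consistency); ``valid_mask`` is the conjunction of both grids'
    data footprints minus any cells invalidated during pairing.
    """

    g1: Grid
    g2: Grid
    hierarchy: ClassHierarchy
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.g1.shape

    @property
    def transform(self) -> GridTransform:
        return self.g1.transform


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = (
    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
)


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        body = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows"):
        if key not in header:
            raise RasterFormatError(f"{path}: ASCII grid missing '{key}' header")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise RasterFormatError(
            f"{path}: body shape {body.shape} != header ({nrows}, {ncols})"
        )
    # cellsize may alternatively come as dx/dy; only square cells supported
    return Grid(
        body,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
        transform=GridTransform(
            header.get("xllcorner", 0.0),
            header.get("yllcorner", 0.0),
            header.get("cellsize", 1.0),
        ),
    )


def _write_ascii(grid: Grid, path: Path, fmt: str) -> None:
    t = grid.transform
    with path.open("w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {t.xllcorner!r}\n")
        fh.write(f"yllcorner {t.yllcorner!r}\n")
        fh.write(f"cellsize {t.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        np.savetxt(fh, grid.values, fmt=fmt)


def _read_tiff(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    return Grid(
        values,
        nodata=meta.get("nodata", DEFAULT_NODATA),
        transform=GridTransform(
            meta.get("xllcorner", 0.0),
            meta.get("yllcorner", 0.0),
            meta.get("cellsize", 1.0),
        ),
        crs_tag=meta.get("crs", ""),
    )


def _write_tiff(grid: Grid, path: Path) -> None:
    import tifffile

    t = grid.transform
    meta = {
        "xllcorner": t.xllcorner,
        "yllcorner": t.yllcorner,
        "cellsize": t.cellsize,
        "nodata": float(grid.nodata),
        "crs": grid.crs_tag,
    }
    tifffile.imwrite(str(path), grid.values, description=json.dumps(meta))


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "tiff"
    return "ascii"


def read_grid(
    path: str | Path, format: Literal["ascii", "tiff"] | None = None
) -> Grid:
    """Read a single-band raster; format inferred from the suffix if omitted."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    fmt = _detect_format(path, format)
    return _read_tiff(path) if fmt == "tiff" else _read_ascii(path)


def read_categorical(
    path: str | Path, format: Literal["ascii", "tiff"] | None = None
) -> Grid:
    """Read a raster of integer class codes.

    Fractional values on valid cells violate the categorical contract and
    raise :class:`RasterFormatError`; the result's dtype is int64.
    """
    grid = read_grid(path, format)
    vals = grid.values
    if np.issubdtype(vals.dtype, np.floating):
        valid = grid.valid_mask
        if np.any(vals[valid] != np.round(vals[valid])):
            raise RasterFormatError(
                f"{path}: non-integral values in a categorical raster"
            )
    out = np.where(grid.valid_mask, vals, grid.nodata).astype(np.int64)
    return Grid(out, int(grid.nodata), grid.transform, grid.crs_tag)


def write_grid(
    grid: Grid,
    path: str | Path,
    format: Literal["ascii", "tiff"] | None = None,
) -> Path:
    """Write a grid; categorical dtypes use integer text formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _detect_format(path, format)
    if fmt == "tiff":
        _write_tiff(grid, path)
    else:
        txt_fmt = "%d" if np.issubdtype(grid.values.dtype, np.integer) else "%.9g"
        _write_ascii(grid, path, txt_fmt)
    return path


def write_surface(
    surface, path: str | Path, format: Literal["ascii", "tiff"] | None = None
) -> Path:
    """Write a metric surface (or bare grid) as float32, nodata-filled.

    Accepts a :class:`Grid` or any object with a ``grid`` attribute (a
    ``MetricSurface``).  Round-trips through :func:`read_grid` within 1e-6
    per cell.
    """
    grid = surface if isinstance(surface, Grid) else surface.grid
    vals = np.where(grid.valid_mask, grid.values, grid.nodata).astype(np.float32)
    return write_grid(replace_values(grid, vals), path, format)


def replace_values(grid: Grid, values: np.ndarray) -> Grid:
    """A grid with the same georeferencing but new cell values."""
    return Grid(values, grid.nodata, grid.transform, grid.crs_tag)


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------


def _parent_lookup(h: ClassHierarchy, child_vals: np.ndarray) -> np.ndarray:
    """Vectorized parent_of over an array of child codes (must all be known)."""
    codes = np.unique(child_vals)
    mapped = np.array([parent_of(h, int(c)) for c in codes], dtype=np.int64)
    idx = np.searchsorted(codes, child_vals)
    return mapped[idx]


def pair_rasters(
    g1: Grid | None,
    g2: Grid,
    hierarchy: ClassHierarchy,
    on_mismatch: Literal["error", "mask", "derive_g1"] | None = None,
) -> CategoricalRasterPair:
    """Pair coarse and fine class rasters into a consistency-checked object.

    Parameters
    ----------
    g1
        Coarse-grade raster, or None to derive it from ``g2`` and the
        hierarchy (``derive_g1`` behaviour).
    on_mismatch
        ``error`` (default when both grids supplied): raise on the first
        vertically inconsistent cell.  ``mask``: drop inconsistent cells
        from the valid mask.  ``derive_g1``: ignore the supplied g1 values
        and rebuild them from g2.
    """
    if on_mismatch is None:
        on_mismatch = "derive_g1" if g1 is None else "error"
    if g1 is None and on_mismatch != "derive_g1":
        raise GridAlignmentError("g1 missing; only derive_g1 mode applies")

    g2_valid = g2.valid_mask
    unknown = np.setdiff1d(
        np.unique(g2.values[g2_valid]), np.fromiter(hierarchy.children, np.int64)
    )
    if unknown.size:
        raise VerticalConsistencyError(
            f"fine-grade codes not in hierarchy: {unknown[:5].tolist()}"
        )

    derived = np.full(g2.shape, DEFAULT_NODATA, dtype=np.int64)
    if g2_valid.any():
        derived[g2_valid] = _parent_lookup(hierarchy, g2.values[g2_valid])

    if on_mismatch == "derive_g1" or g1 is None:
        transform = g2.transform if g1 is None else g1.transform
        g1_out = Grid(derived, DEFAULT_NODATA, transform, g2.crs_tag)
        return CategoricalRasterPair(g1_out, g2, hierarchy, g2_valid.copy())

    if g1.shape != g2.shape:
        raise GridAlignmentError(f"shape mismatch: g1 {g1.shape} vs g2 {g2.shape}")
    if not g1.transform.close_to(g2.transform):
        raise GridAlignmentError("geotransform mismatch between g1 and g2")
    if not np.array_equal(g1.valid_mask, g2_valid):
        raise GridAlignmentError("nodata footprints of g1 and g2 differ")

    consistent = np.ones(g2.shape, dtype=bool)
    consistent[g2_valid] = g1.values[g2_valid] == derived[g2_valid]
    if on_mismatch == "error":
        bad = np.argwhere(~consistent)
        if bad.size:
            r, c = bad[0]
            raise VerticalConsistencyError(
                f"cell ({r}, {c}): g2 code {g2.values[r, c]} maps to parent "
                f"{derived[r, c]} but g1 holds {g1.values[r, c]}"
            )
        valid = g2_valid.copy()
    else:  # mask
        valid = g2_valid & consistent
    return CategoricalRasterPair(g1, g2, hierarchy, valid)
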