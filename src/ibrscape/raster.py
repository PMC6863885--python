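"""Georeferenced raster grids and ESRI ASCII grid I/O.

All layers in one analysis share a single projected CRS (coordinates in
meters); a :class:`RasterGrid` is a plain 2-D array plus the affine metadata
needed to map cell indices to coordinates.  Row 0 is the *top* row of the
map, as in the ESRI ASCII convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterGrid:
    """A single raster layer (categorical codes or continuous values).

    Parameters
    ----------
    data : ndarray, shape (nrows, ncols)
        Cell values; ``nodata`` marks missing cells.
    xll, yll : float
        Coordinates of the lower-left corner of the lower-left cell (m).
    cell_size : float
        Square cell edge length (m), > 0.
    nodata : float
        Missing-value code.
    name : str
        Layer name ("landcover", "bio06", ...).
    year : int | None
        Year tag for multi-year categorical layers.
    """

    data: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cell_size: float = 1.0
    nodata: float = -9999.0
    name: str = "layer"
    year: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the full grid."""
        nr, nc = self.data.shape
        return (self.xll, self.xll + nc * self.cell_size,
                self.yll, self.yll + nr * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of all cell centers, shape (nrows, ncols)."""
        nr, nc = self.data.shape
        xs = self.xll + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.yll + (nr - np.arange(nr) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing point (x, y)."""
        nr, nc = self.data.shape
        col = int(np.floor((x - self.xll) / self.cell_size))
        row = int(nr - 1 - np.floor((y - self.yll) / self.cell_size))
        if not (0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"point ({x}, {y}) outside raster bounds")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        nr = self.data.shape[0]
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.yll + (nr - row - 0.5) * self.cell_size
        return x, y

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.xll, other.xll)
                and np.isclose(self.yll, other.yll)
                and np.isclose(self.cell_size, other.cell_size))

    def copy_with(self, **kw) -> "RasterGrid":
        if "data" not in kw:
            kw["data"] = self.data.copy()
        return replace(self, **kw)


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    path = Path(path)
    data = np.asarray(grid.data, dtype=float)
    nr, nc = data.shape
    out = np.where(np.isnan(data), grid.nodata, data)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in out:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")
    return path


def read_ascii_grid(path: str | Path, name: str | None = None,
                    year: int | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter"}:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    body = " ".join(lines[i:])
    data = np.array(body.split(), dtype=float)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nr, nc)
    cell = header["cellsize"]
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cell / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cell / 2)
    nodata = header.get("nodata_value", -9999.0)
    return RasterGrid(data=data, xll=xll, yll=yll, cell_size=cell,
                      nodata=nodata, name=name or path.stem, year=year)
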