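"""Regular planar raster grids.

All coordinates are projected planar meters. Grids are origin-anchored at
the upper-left corner, row-major, top-left cell first; point-in-cell
lookups use the cell-center convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSpec", "RasterGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: shape, upper-left origin, cell size (m)."""

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be positive")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of cell centers, each shaped (n_rows, n_cols)."""
        cs = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid bounds")
        return row, col

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edge."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )


@dataclass
class RasterGrid:
    """2-D cell values on a :class:`GridSpec` with a nodata mask.

    ``mask`` is True where a cell is nodata. ``values`` at masked cells are
    undefined and never read by any operation.
    """

    values: np.ndarray
    spec: GridSpec
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("values shape does not match grid spec")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
            self.mask = self.mask | ~np.isfinite(self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def same_grid(self, other: "RasterGrid") -> bool:
        return self.spec == other.spec

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            spec=self.spec,
            mask=self.mask.copy(),
            name=self.name if name is None else name,
        )

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.spec, self.mask.copy(), self.name)


_NODATA = -9999.0


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc). Values are written at full precision."""
    spec = grid.spec
    vals = grid.values.copy()
    vals[grid.mask] = _NODATA
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y - spec.n_rows * spec.cell_size!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(format(float(v), ".17g") for v in row) + "\n")


def read_ascii_grid(path, name: str = "") -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {req!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.array(rows, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
    )
    nodata = header.get("nodata_value", _NODATA)
    mask = values == nodata
    return RasterGrid(values=values, spec=spec, mask=mask, name=name)
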