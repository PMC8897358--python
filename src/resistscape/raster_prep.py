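"""Covariate-stack preparation.

Builds the analysis-ready predictor stack: raster IO, resampling onto the
analysis grid, inverse-distance-weighted interpolation of weather-station
points, the study extent (minimum convex polygon around the sampling sites
plus an external buffer), the host-cover-minus-defoliation merge, and a
variance-inflation-factor collinearity screen.

Station and site tables are plain pandas DataFrames with columns
``station, x, y, value`` and ``site, x, y, n`` respectively (projected
meters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, Polygon

from .grids import GridSpec, RasterGrid, read_ascii_grid, write_ascii_grid

__all__ = [
    "CovariateDiagnostics",
    "read_raster",
    "write_raster",
    "resample_to_grid",
    "idw_interpolate",
    "mcp_buffer_extent",
    "merge_host_defoliation",
    "vif_filter",
    "assert_grid_consistent",
]


def read_raster(path, name: str | None = None) -> RasterGrid:
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd"):
        return read_ascii_grid(path, name=name or path.stem)
    raise ValueError(
        f"unsupported raster format {path.suffix!r}; supply an ESRI ASCII "
        "grid (.asc) in projected planar meters"
    )


def write_raster(grid: RasterGrid, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".asc", ".agr", ".grd"):
        write_ascii_grid(grid, path)
        return
    raise ValueError(f"unsupported raster format {path.suffix!r}; use .asc")


def resample_to_grid(grid: RasterGrid, target: GridSpec, method: str) -> RasterGrid:
    """Resample ``grid`` onto ``target``.

    ``mean-aggregate`` block-averages a fine grid onto a coarser aligned grid
    (cell sizes in integer ratio); it conserves the spatial mean over fully
    covered regions. ``bilinear`` interpolates a coarse grid onto a finer one.
    """
    src = grid.spec
    sxmin, symin, sxmax, symax = src.bounds
    txmin, tymin, txmax, tymax = target.bounds
    if txmin >= sxmax or txmax <= sxmin or tymin >= symax or tymax <= symin:
        raise ValueError("target grid does not overlap source raster")

    if method == "mean-aggregate":
        ratio = target.cell_size / src.cell_size
        k = int(round(ratio))
        if k < 1 or abs(ratio - k) > 1e-9:
            raise ValueError(
                "mean-aggregate requires the target cell size to be an "
                "integer multiple of the source cell size"
            )
        # offset of the target origin inside the source grid, in source cells
        ox = (target.origin_x - src.origin_x) / src.cell_size
        oy = (src.origin_y - target.origin_y) / src.cell_size
        if abs(ox - round(ox)) > 1e-9 or abs(oy - round(oy)) > 1e-9:
            raise ValueError("mean-aggregate requires cell-aligned grids")
        ox, oy = int(round(ox)), int(round(oy))
        out = np.full((target.n_rows, target.n_cols), np.nan)
        vals = np.where(grid.mask, np.nan, grid.values)
        for r in range(target.n_rows):
            for c in range(target.n_cols):
                r0, c0 = oy + r * k, ox + c * k
                block = vals[max(r0, 0):r0 + k, max(c0, 0):c0 + k]
                if block.size and np.isfinite(block).any():
                    out[r, c] = np.nanmean(block)
        return RasterGrid(out, target, mask=~np.isfinite(out), name=grid.name)

    if method == "bilinear":
        from scipy.interpolate import RegularGridInterpolator

        cs = src.cell_size
        ys = src.origin_y - (np.arange(src.n_rows) + 0.5) * cs
        xs = src.origin_x + (np.arange(src.n_cols) + 0.5) * cs
        vals = np.where(grid.mask, np.nan, grid.values)
        interp = RegularGridInterpolator(
            (ys[::-1], xs), vals[::-1, :], method="linear",
            bounds_error=False, fill_value=None,
        )
        tx, ty = target.cell_centers()
        pts = np.column_stack([ty.ravel(), tx.ravel()])
        out = interp(pts).reshape(target.n_rows, target.n_cols)
        return RasterGrid(out, target, mask=~np.isfinite(out), name=grid.name)

    raise ValueError(f"unknown resampling method {method!r}")


def idw_interpolate(
    stations: pd.DataFrame, target: GridSpec, power: float = 2.0
) -> RasterGrid:
    """Inverse-distance-weighted interpolation of station values onto a grid.

    Cell value = sum(w_k z_k) / sum(w_k) with w_k = d_k**(-power). A cell
    whose center coincides with a station takes that station's value exactly.
    """
    if len(stations) < 1:
        raise ValueError("at least one station required")
    if not power > 0:
        raise ValueError("power must be positive")
    pts = stations[["x", "y"]].to_numpy(dtype=float)
    vals = stations["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("station values must be finite")
    # duplicate coordinates with conflicting values are ambiguous
    _, inv = np.unique(pts.round(9), axis=0, return_inverse=True)
    for g in range(inv.max() + 1):
        sel = vals[inv == g]
        if len(sel) > 1 and np.ptp(sel) > 0:
            raise ValueError("duplicate station coordinates with conflicting values")

    gx, gy = target.cell_centers()
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    d = cdist(centers, pts)
    out = np.empty(len(centers))
    exact = d < 1e-9
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[has_exact] = 0.0
    num = w @ vals
    den = w.sum(axis=1)
    out[~has_exact] = num[~has_exact] / den[~has_exact]
    if has_exact.any():
        idx = exact[has_exact].argmax(axis=1)
        out[has_exact] = vals[idx]
    values = out.reshape(target.n_rows, target.n_cols)
    return RasterGrid(values, target, mask=np.zeros_like(values, bool), name="idw")


def mcp_buffer_extent(sites: pd.DataFrame, buffer_m: float) -> Polygon:
    """Minimum convex polygon around the sites, dilated by ``buffer_m``.

    The study extent of the analysis: all sampling sites lie strictly inside
    whenever the buffer is positive.
    """
    pts = sites[["x", "y"]].drop_duplicates().to_numpy(dtype=float)
    if len(pts) < 3:
        raise ValueError(
            "need at least 3 sites for a convex polygon; for fewer sites "
            "use a bounding-box extent instead"
        )
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError(
            "sites are collinear; cannot form a convex polygon — use a "
            "bounding-box extent instead"
        )
    if buffer_m < 0:
        raise ValueError("buffer must be non-negative")
    return hull if buffer_m == 0 else hull.buffer(buffer_m, quad_segs=64)


def merge_host_defoliation(host: RasterGrid, defol: RasterGrid) -> RasterGrid:
    """Net host cover: host percentage minus defoliation percentage, floored at 0."""
    if not host.same_grid(defol):
        raise ValueError("host and defoliation rasters are on different grids")
    out = np.clip(host.values - defol.values, 0.0, None)
    return RasterGrid(out, host.spec, mask=host.mask | defol.mask, name="host_cover_net")


@dataclass
class CovariateDiagnostics:
    """Result of the iterative VIF screen."""

    vif: dict[str, float]            # VIF at the step each covariate was assessed last
    threshold: float
    kept: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)  # in removal order

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "vif": {k: (None if np.isinf(v) else v) for k, v in self.vif.items()},
            "kept": self.kept,
            "dropped": self.dropped,
        }


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R² of column j on the remaining columns)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - resid @ resid / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_filter(stack: list[RasterGrid], threshold: float = 2.5) -> CovariateDiagnostics:
    """Iteratively drop the highest-VIF covariate until all VIFs ≤ threshold.

    VIFs are computed over the cells jointly valid across the stack. Exactly
    collinear covariates report infinite VIF and are dropped first.
    """
    if len(stack) < 2:
        raise ValueError("VIF screening needs at least 2 covariates")
    assert_grid_consistent(stack)
    valid = np.logical_and.reduce([g.valid for g in stack])
    if not valid.any():
        raise ValueError("no cells jointly valid across the stack")
    names = [g.name or f"cov{i}" for i, g in enumerate(stack)]
    X = np.column_stack([g.values[valid] for g in stack])

    diag = CovariateDiagnostics(vif={}, threshold=threshold, kept=list(names))
    while len(diag.kept) >= 2:
        cols = [names.index(n) for n in diag.kept]
        vifs = np.array([_vif_one(X[:, cols], i) for i in range(len(cols))])
        for n, v in zip(diag.kept, vifs):
            diag.vif[n] = float(v)
        # ties (e.g. several exactly collinear layers) drop the later-listed
        # covariate, so derived layers lose to the layers they came from
        worst = len(vifs) - 1 - int(np.argmax(vifs[::-1]))
        if vifs[worst] <= threshold:
            break
        victim = diag.kept.pop(worst)
        diag.dropped.append(victim)
        if np.isinf(vifs[worst]):
            warnings.warn(
                f"covariate {victim!r} is exactly collinear with the others "
                "(infinite VIF); dropped",
                stacklevel=2,
            )
    return diag


def assert_grid_consistent(stack: list[RasterGrid]) -> None:
    """Raise if the rasters in ``stack`` are not on one shared grid."""
    if not stack:
        raise ValueError("empty raster stack")
    ref = stack[0].spec
    for g in stack[1:]:
        if g.spec != ref:
            raise ValueError(
                f"raster {g.name!r} is on a different grid than {stack[0].name!r}"
            )
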