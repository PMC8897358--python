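"""Cumulative passage maps, corridors, and future-scenario projection.

Source/destination nodes are placed on a regular lattice over the
buffered study extent; the randomized-shortest-paths net passages are
summed over all unordered node pairs, the buffer is cropped after
summation to remove edge effects, and the top fraction of connectivity
values defines the corridor mask. Scenario projection rebuilds the
resistance surfaces from the stored transformation parameters of the
replicate-run top models with one or more covariates swapped for their
scenario counterparts, averages the per-pixel resistances, and reruns the
mapping; the difference map is future minus present.

At the random-walk setting (theta at or below the circuit tolerance) the
all-pairs sum is computed from one grounded-Laplacian factorization and
one solve per node (all targets handled per source by superposition of
the potential columns), which equals the pair-by-pair computation
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Point, Polygon, box

from .effective_distance import (
    RSPConfig,
    TransitionGraph,
    _grounded_solver,
    _rsp_net_edge_flows,
    build_transition_graph,
)
from .grids import RasterGrid
from .optimizer import SurfaceModel, surface_from_model
from .resistance_transforms import ResistanceSurface, average_surfaces

__all__ = [
    "NodeGrid",
    "PassageMap",
    "place_node_grid",
    "cumulative_passage_map",
    "corridor_mask",
    "project_future",
    "difference_map",
]


@dataclass
class NodeGrid:
    """Regularly spaced nodes snapped to valid cell centers."""

    coords: np.ndarray              # (k, 2) x, y
    cells: np.ndarray               # (k, 2) row, col
    spacing: float
    n_requested: int
    n_dropped_nodata: int = 0

    @property
    def count(self) -> int:
        return len(self.coords)


@dataclass
class PassageMap:
    grid: RasterGrid
    n_nodes: int
    theta: float
    buffer_cropped: bool = False


def place_node_grid(
    extent: Polygon,
    buffer_m: float,
    n_nodes: int,
    surface: ResistanceSurface,
) -> NodeGrid:
    """Square lattice of ~``n_nodes`` nodes within the buffered extent.

    Spacing is chosen so the in-extent lattice count lands within 5% of
    the request where geometry allows; nodes are snapped to cell centers
    and nodes falling on nodata cells are dropped and counted.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    buffered = extent.buffer(buffer_m) if buffer_m > 0 else extent
    spec = surface.grid.spec
    buffered = buffered.intersection(box(*spec.bounds))
    if buffered.is_empty:
        raise ValueError("buffered extent does not intersect the raster")
    area = buffered.area
    spacing = float(np.sqrt(area / n_nodes))

    def lattice(h: float) -> np.ndarray:
        xmin, ymin, xmax, ymax = buffered.bounds
        xs = np.arange(xmin + h / 2, xmax, h)
        ys = np.arange(ymin + h / 2, ymax, h)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = np.array([buffered.contains(Point(*p)) for p in pts])
        return pts[inside]

    pts = lattice(spacing)
    for _ in range(25):
        if len(pts) == 0:
            spacing *= 0.7
            pts = lattice(spacing)
            continue
        ratio = len(pts) / n_nodes
        if abs(ratio - 1.0) <= 0.05:
            break
        spacing *= np.sqrt(ratio)
        pts = lattice(spacing)

    cells, coords, seen = [], [], set()
    dropped = 0
    for x, y in pts:
        try:
            r, c = spec.cell_of(x, y)
        except ValueError:
            dropped += 1
            continue
        if surface.grid.mask[r, c]:
            dropped += 1
            continue
        if (r, c) in seen:
            continue
        seen.add((r, c))
        cells.append((r, c))
        cx = spec.origin_x + (c + 0.5) * spec.cell_size
        cy = spec.origin_y - (r + 0.5) * spec.cell_size
        coords.append((cx, cy))
    if len(coords) < 2:
        raise ValueError("fewer than 2 placeable nodes inside the buffered extent")
    return NodeGrid(
        coords=np.array(coords),
        cells=np.array(cells),
        spacing=spacing,
        n_requested=n_nodes,
        n_dropped_nodata=dropped,
    )


def _restrict_to_component(
    graph: TransitionGraph, node_ids: np.ndarray
) -> np.ndarray:
    n_comp, labels = connected_components(graph.adjacency(), directed=False)
    if n_comp == 1:
        return node_ids
    lab = labels[node_ids]
    vals, counts = np.unique(lab, return_counts=True)
    major = vals[np.argmax(counts)]
    if (lab != major).any():
        warnings.warn(
            f"{(lab != major).sum()} nodes fall outside the largest connected "
            "component and are excluded from the passage map",
            stacklevel=3,
        )
    return node_ids[lab == major]


def _allpairs_circuit_passages(
    graph: TransitionGraph, node_ids: np.ndarray
) -> np.ndarray:
    """Sum of per-pair circuit net passages over all unordered pairs.

    One grounded factorization; potential columns per node; per source the
    pair currents over its later-listed targets are superposed columnwise.
    Identical to looping rsp_net_passages at the circuit setting.
    """
    ground = int(node_ids[0])
    solve = _grounded_solver(graph.laplacian(), ground=ground)
    B = np.zeros((graph.n_nodes, len(node_ids)))
    B[node_ids, np.arange(len(node_ids))] = 1.0
    phi = solve(B)                          # (n_nodes, k) potential columns
    ei, ej, cond = graph.edge_i, graph.edge_j, graph.conductance
    inc = sp.coo_matrix(
        (
            np.ones(2 * len(ei)),
            (np.r_[ei, ej], np.r_[np.arange(len(ei)), np.arange(len(ei))]),
        ),
        shape=(graph.n_nodes, len(ei)),
    ).tocsr()
    total = np.zeros(graph.n_nodes)
    k = len(node_ids)
    for a in range(k - 1):
        V = phi[:, a][:, None] - phi[:, a + 1:]          # (n_nodes, k-1-a)
        I = cond[:, None] * (V[ei, :] - V[ej, :])        # per-edge currents
        total += inc @ np.abs(I).sum(axis=1)
        # unit injections: source and each target get |b_v| = 1 per pair
        total[node_ids[a]] += k - 1 - a
        total[node_ids[a + 1:]] += 1.0
    return 0.5 * total


def cumulative_passage_map(
    surface: ResistanceSurface,
    nodes: NodeGrid,
    cfg: RSPConfig,
    crop_extent: Polygon | None = None,
) -> PassageMap:
    """Total net passages per cell, summed over all unordered node pairs.

    If ``crop_extent`` is given (the unbuffered study extent), cells whose
    centers fall outside it are masked after summation; interior values
    are untouched.
    """
    graph = build_transition_graph(surface)
    node_ids = np.array([graph.node_at(r, c) for r, c in nodes.cells])
    node_ids = _restrict_to_component(graph, node_ids)
    if len(node_ids) < 2:
        raise ValueError("fewer than 2 connected nodes")
    if cfg.theta <= cfg.circuit_tolerance:
        totals = _allpairs_circuit_passages(graph, node_ids)
    else:
        totals = np.zeros(graph.n_nodes)
        from .effective_distance import _passages_from_net_edge_flow

        for a in range(len(node_ids) - 1):
            for b in range(a + 1, len(node_ids)):
                s, t = int(node_ids[a]), int(node_ids[b])
                net = _rsp_net_edge_flows(graph, s, t, cfg.theta)
                totals += _passages_from_net_edge_flow(graph, net, s, t)
    out = graph.grid_from_node_values(totals, name="cumulative_passages")
    cropped = False
    if crop_extent is not None:
        gx, gy = out.spec.cell_centers()
        inside = np.array([
            crop_extent.contains(Point(x, y))
            for x, y in zip(gx.ravel(), gy.ravel())
        ]).reshape(gx.shape)
        out.mask |= ~inside
        cropped = True
    return PassageMap(grid=out, n_nodes=len(node_ids), theta=cfg.theta,
                      buffer_cropped=cropped)


def corridor_mask(pm: PassageMap, keep_fraction: float = 0.5) -> RasterGrid:
    """Binary corridor: valid cells at or above the (1 - keep) quantile.

    Quantiles use linear interpolation; ties at the threshold are kept.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must lie in (0, 1]")
    vals = pm.grid.valid_values()
    thr = np.quantile(vals, 1.0 - keep_fraction)
    out = (pm.grid.values >= thr).astype(float)
    return RasterGrid(out, pm.grid.spec, mask=pm.grid.mask.copy(), name="corridor")


def project_future(
    models: list[SurfaceModel],
    future_covariates: dict[str, RasterGrid],
    static_covariates: dict[str, RasterGrid],
    nodes: NodeGrid,
    cfg: RSPConfig,
    crop_extent: Polygon | None = None,
) -> PassageMap:
    """Connectivity under a covariate swap.

    Each replicate-run model is re-applied with its stored transformation
    parameters to the scenario stack (future covariates take precedence,
    anything else falls back to the static present layer); resistances are
    averaged per pixel across models and the passage map is rerun.
    """
    if not models:
        raise ValueError("need at least one stored model")
    stack = {**static_covariates, **future_covariates}
    surfaces = []
    for m in models:
        for name, _, _ in m.parts:
            if name not in stack:
                raise ValueError(f"scenario is missing covariate {name!r}")
        surfaces.append(surface_from_model(m, stack))
    avg = average_surfaces(surfaces)
    return cumulative_passage_map(avg, nodes, cfg, crop_extent=crop_extent)


def difference_map(future: PassageMap, present: PassageMap) -> RasterGrid:
    """Cellwise future minus present passages."""
    if future.grid.spec != present.grid.spec:
        raise ValueError("passage maps are on different grids")
    if future.n_nodes != present.n_nodes or future.theta != present.theta:
        raise ValueError("passage maps use different node designs")
    mask = future.grid.mask | present.grid.mask
    return RasterGrid(
        future.grid.values - present.grid.values,
        future.grid.spec,
        mask=mask,
        name="connectivity_difference",
    )
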