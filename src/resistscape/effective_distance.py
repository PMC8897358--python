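"""Effective distances on the raster movement graph.

Cells of a resistance surface become nodes of an 8-neighbor (queen) graph.
Edge conductance is the arithmetic mean of the two cells' conductances
(1 / resistance) divided by the center-to-center distance, so diagonal
edges are down-weighted by sqrt(2); edge cost is the length-weighted mean
resistance, the reciprocal convention of the same construction.

Two quantities are computed on this graph:

* random-walk commute distances C(i, j) = vol(G) * R_eff(i, j), the
  optimization-stage effective distance, via grounded graph-Laplacian
  solves;
* randomized-shortest-paths (RSP) expected net passages for a unit
  source -> target transition, the mapping-stage quantity. The RSP family
  interpolates between the pure random walk (theta -> 0, equivalent to
  circuit current flow) and the least-cost path (theta large) by Boltzmann
  reweighting of walk probabilities by path cost. Below
  ``circuit_tolerance`` the exact circuit (Laplacian) formulation is used;
  the two limits coincide analytically and the exact RSP solve is
  ill-conditioned at very small theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import splu

from .grids import RasterGrid
from .resistance_transforms import ResistanceSurface

__all__ = [
    "RSPConfig",
    "TransitionGraph",
    "build_transition_graph",
    "commute_distance_matrix",
    "rsp_net_passages",
    "least_cost_path_nodes",
]


@dataclass(frozen=True)
class RSPConfig:
    """RSP tuning: inverse temperature ``theta`` in (0, 20).

    theta -> 0 recovers the random walk / circuit model; theta large
    approaches the least-cost path. ``circuit_tolerance`` is the theta
    below which the exact circuit formulation is used.
    """

    theta: float = 1e-6
    circuit_tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.theta < 20):
            raise ValueError("theta must lie strictly between 0 and 20")


@dataclass
class TransitionGraph:
    """Sparse symmetric movement graph over valid raster cells."""

    node_of_cell: np.ndarray       # (n_rows, n_cols) int, -1 for nodata
    cells: np.ndarray              # (n_nodes, 2) row, col per node
    edge_i: np.ndarray
    edge_j: np.ndarray
    conductance: np.ndarray        # per edge, > 0
    cost: np.ndarray               # per edge, length-weighted resistance
    surface: ResistanceSurface

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    def adjacency(self, weights: np.ndarray | None = None) -> sp.csr_matrix:
        w = self.conductance if weights is None else weights
        n = self.n_nodes
        a = sp.coo_matrix(
            (np.r_[w, w], (np.r_[self.edge_i, self.edge_j],
                           np.r_[self.edge_j, self.edge_i])),
            shape=(n, n),
        )
        return a.tocsr()

    def laplacian(self) -> sp.csr_matrix:
        a = self.adjacency()
        d = np.asarray(a.sum(axis=1)).ravel()
        return (sp.diags(d) - a).tocsr()

    @property
    def volume(self) -> float:
        """Total node degree: twice the summed edge conductance."""
        return 2.0 * float(self.conductance.sum())

    def node_at(self, row: int, col: int) -> int:
        node = int(self.node_of_cell[row, col])
        if node < 0:
            raise ValueError(f"cell ({row}, {col}) is nodata; no graph node")
        return node

    def grid_from_node_values(self, values: np.ndarray, name: str = "") -> RasterGrid:
        spec = self.surface.grid.spec
        out = np.full((spec.n_rows, spec.n_cols), np.nan)
        out[self.cells[:, 0], self.cells[:, 1]] = values
        return RasterGrid(out, spec, mask=self.surface.grid.mask.copy(), name=name)


_OFFSETS = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0)))


def build_transition_graph(
    r: ResistanceSurface, conductance_mean: str = "arithmetic"
) -> TransitionGraph:
    """Queen-neighborhood transition graph from a resistance surface."""
    grid = r.grid
    valid = grid.valid
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells to build a graph")
    node_of_cell = np.full(grid.values.shape, -1, dtype=int)
    rows, cols = np.nonzero(valid)
    node_of_cell[rows, cols] = np.arange(len(rows))
    cells = np.column_stack([rows, cols])
    res = grid.values
    cs = grid.spec.cell_size

    ei, ej, cond, cost = [], [], [], []
    nr, nc = grid.values.shape
    for dr, dc, mult in _OFFSETS:
        r0 = slice(0, nr - dr)
        r1 = slice(dr, nr)
        c0 = slice(max(0, -dc), nc - max(0, dc))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        ok = valid[r0, c0] & valid[r1, c1]
        a = node_of_cell[r0, c0][ok]
        b = node_of_cell[r1, c1][ok]
        ra = res[r0, c0][ok]
        rb = res[r1, c1][ok]
        dist = cs * mult
        if conductance_mean == "arithmetic":
            c = 0.5 * (1.0 / ra + 1.0 / rb) / dist
        elif conductance_mean == "harmonic":
            c = 2.0 / (ra + rb) / dist
        else:
            raise ValueError(f"unknown conductance mean {conductance_mean!r}")
        ei.append(a)
        ej.append(b)
        cond.append(c)
        cost.append(dist * 0.5 * (ra + rb))
    return TransitionGraph(
        node_of_cell=node_of_cell,
        cells=cells,
        edge_i=np.concatenate(ei),
        edge_j=np.concatenate(ej),
        conductance=np.concatenate(cond),
        cost=np.concatenate(cost),
        surface=r,
    )


def _component_of(g: TransitionGraph, nodes: np.ndarray) -> np.ndarray:
    """Labels of connected components; raises if ``nodes`` span several."""
    n_comp, labels = connected_components(g.adjacency(), directed=False)
    if n_comp > 1:
        lab = labels[nodes]
        if len(set(lab.tolist())) > 1:
            groups = {}
            for nd, l in zip(nodes.tolist(), lab.tolist()):
                groups.setdefault(l, []).append(nd)
            raise ValueError(
                f"query nodes fall in {len(groups)} disconnected components: {groups}"
            )
    return labels


def _grounded_solver(L: sp.spmatrix, ground: int):
    """LU solver of the Laplacian with row/col ``ground`` removed."""
    n = L.shape[0]
    keep = np.r_[0:ground, ground + 1:n]
    Lg = L[keep][:, keep].tocsc()
    lu = splu(Lg)

    def solve(b: np.ndarray) -> np.ndarray:
        """Solve L_g x = b (full-length b; ground row dropped, re-inserted as 0)."""
        bg = b[keep] if b.ndim == 1 else b[keep, :]
        xg = lu.solve(np.ascontiguousarray(bg))
        if b.ndim == 1:
            x = np.zeros(n)
            x[keep] = xg
        else:
            x = np.zeros((n, b.shape[1]))
            x[keep, :] = xg
        return x

    return solve


def commute_distance_matrix(g: TransitionGraph, sites: np.ndarray) -> np.ndarray:
    """Random-walk commute distances C(i,j) = vol(G) * R_eff(i,j) between sites.

    R_eff is the two-point effective resistance from grounded Laplacian
    solves; the result is symmetric with zero diagonal. All site nodes must
    lie in a single connected component.
    """
    sites = np.asarray(sites, dtype=int)
    if len(sites) < 2:
        raise ValueError("need at least 2 site nodes")
    labels = _component_of(g, sites)
    comp = labels[sites[0]]
    in_comp = labels == comp
    # restrict to the component so the grounded Laplacian is nonsingular
    idx_map = -np.ones(g.n_nodes, dtype=int)
    idx_map[in_comp] = np.arange(in_comp.sum())
    keep_e = in_comp[g.edge_i]
    sub = sp.coo_matrix(
        (
            np.r_[g.conductance[keep_e], g.conductance[keep_e]],
            (
                np.r_[idx_map[g.edge_i[keep_e]], idx_map[g.edge_j[keep_e]]],
                np.r_[idx_map[g.edge_j[keep_e]], idx_map[g.edge_i[keep_e]]],
            ),
        ),
        shape=(in_comp.sum(),) * 2,
    ).tocsr()
    deg = np.asarray(sub.sum(axis=1)).ravel()
    L = sp.diags(deg) - sub
    vol = float(deg.sum())
    s = idx_map[sites]
    solve = _grounded_solver(L.tocsr(), ground=int(s[0]))
    B = np.zeros((L.shape[0], len(s)))
    B[s, np.arange(len(s))] = 1.0
    V = solve(B)  # V[:, k] = L_g^+ e_{site_k}; ground column is all zero
    # R_eff(i, j) = V[i,i] + V[j,j] - V[i,j] - V[j,i]
    Vss = V[s, :]
    d = np.diag(Vss)
    reff = d[:, None] + d[None, :] - Vss - Vss.T
    C = vol * reff
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 0.0)
    return C


def _passages_from_net_edge_flow(
    g: TransitionGraph, net: np.ndarray, source: int, target: int
) -> np.ndarray:
    """Node throughflow from signed per-edge flows (i -> j positive).

    Passage(v) = (sum of |flow| over incident edges + |injection|) / 2, so a
    unit transition scores 1 at both endpoints and the flow through each
    intermediate cell elsewhere.
    """
    out = np.zeros(g.n_nodes)
    np.add.at(out, g.edge_i, np.abs(net))
    np.add.at(out, g.edge_j, np.abs(net))
    out[source] += 1.0
    out[target] += 1.0
    return 0.5 * out


def _circuit_net_edge_flows(
    g: TransitionGraph, solve, source: int, target: int
) -> np.ndarray:
    b = np.zeros(g.n_nodes)
    b[source] = 1.0
    b[target] = -1.0
    v = solve(b)
    return g.conductance * (v[g.edge_i] - v[g.edge_j])


def rsp_net_passages(
    g: TransitionGraph, source: int, target: int, cfg: RSPConfig
) -> RasterGrid:
    """Expected net passages per cell for a unit source -> target transition."""
    if source == target:
        raise ValueError("source and target must differ")
    _component_of(g, np.array([source, target]))
    if cfg.theta <= cfg.circuit_tolerance:
        solve = _grounded_solver(g.laplacian(), ground=target)
        net = _circuit_net_edge_flows(g, solve, source, target)
    else:
        net = _rsp_net_edge_flows(g, source, target, cfg.theta)
    vals = _passages_from_net_edge_flow(g, net, source, target)
    return g.grid_from_node_values(vals, name="net_passages")


def _rsp_net_edge_flows(
    g: TransitionGraph, source: int, target: int, theta: float
) -> np.ndarray:
    """Expected net edge flows under the randomized-shortest-paths model.

    Reference walk transition probabilities come from the conductances;
    each step is reweighted by exp(-theta * edge cost) with the target made
    absorbing. Expected edge flows follow from fundamental-matrix solves:
    n(i->j) = z_s(i) * W_ij * z_t(j) / z_st.
    """
    n = g.n_nodes
    A = g.adjacency()
    deg = np.asarray(A.sum(axis=1)).ravel()
    ii = np.r_[g.edge_i, g.edge_j]
    jj = np.r_[g.edge_j, g.edge_i]
    cc = np.r_[g.conductance, g.conductance]
    kk = np.r_[g.cost, g.cost]
    p_ref = cc / deg[ii]
    w = p_ref * np.exp(-theta * kk)
    keep = ii != target  # absorbing target: no transitions out of it
    W = sp.coo_matrix((w[keep], (ii[keep], jj[keep])), shape=(n, n)).tocsc()
    M = (sp.eye(n) - W).tocsc()
    lu = splu(M)
    e_t = np.zeros(n)
    e_t[target] = 1.0
    zcol = lu.solve(e_t)            # zcol[i] = Z_{i,target}
    e_s = np.zeros(n)
    e_s[source] = 1.0
    zrow = splu(M.T.tocsc()).solve(e_s)  # zrow[j] = Z_{source,j}
    z_st = zcol[source]
    if not np.isfinite(z_st) or z_st <= 0:
        raise ValueError(
            "RSP solve degenerate (z_st <= 0); graph disconnected or theta "
            "too large for the cost scale"
        )
    W = W.tocoo()
    flow = np.zeros(2 * len(g.edge_i))
    # match COO entries back to directed-edge slots
    key_all = ii.astype(np.int64) * n + jj
    order = np.argsort(key_all, kind="stable")
    key_W = W.row.astype(np.int64) * n + W.col
    pos = order[np.searchsorted(key_all[order], key_W)]
    flow[pos] = zrow[W.row] * W.data * zcol[W.col] / z_st
    m = len(g.edge_i)
    return flow[:m] - flow[m:]


def least_cost_path_nodes(g: TransitionGraph, source: int, target: int) -> np.ndarray:
    """Nodes on the least-cost path (Dijkstra on edge costs); oracle utility."""
    n = g.n_nodes
    A = sp.coo_matrix(
        (np.r_[g.cost, g.cost], (np.r_[g.edge_i, g.edge_j],
                                 np.r_[g.edge_j, g.edge_i])),
        shape=(n, n),
    ).tocsr()
    _, pred = dijkstra(A, directed=False, indices=[source], return_predecessors=True)
    path = [target]
    while path[-1] != source:
        p = pred[0, path[-1]]
        if p < 0:
            raise ValueError("no path between source and target")
        path.append(int(p))
    return np.array(path[::-1])
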