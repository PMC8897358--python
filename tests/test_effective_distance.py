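import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from resistscape import (
    RSPConfig,
    TransitionGraph,
    build_transition_graph,
    commute_distance_matrix,
    rsp_net_passages,
)
from resistscape.effective_distance import least_cost_path_nodes

from conftest import laplacian_pseudoinverse, make_surface, random_surface


class TestTransitionGraph:
    def test_uniform_surface_unit_conductances(self):
        g = build_transition_graph(make_surface(np.ones((2, 2))))
        # rook edges: mean(1, 1) / 1 = 1; diagonal: 1 / sqrt(2)
        rook = g.conductance[np.isclose(g.cost, 1.0)]
        diag = g.conductance[np.isclose(g.cost, np.sqrt(2))]
        np.testing.assert_allclose(rook, 1.0)
        np.testing.assert_allclose(diag, 1.0 / np.sqrt(2))
        assert len(rook) == 4 and len(diag) == 2

    def test_masked_cell_has_no_edges(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        g = build_transition_graph(make_surface(np.ones((3, 3)), mask=mask))
        assert np.all(g.node_of_cell[1, 1] == -1)
        # center absent: only perimeter edges remain
        assert g.n_nodes == 8

    def test_edge_list_matches_enumeration_oracle(self, rng):
        surf = random_surface(rng, 4)
        g = build_transition_graph(surf)
        oracle = set()
        res = surf.grid.values
        for r in range(4):
            for c in range(4):
                for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < 4 and 0 <= c2 < 4:
                        dist = np.hypot(dr, dc)
                        cond = 0.5 * (1 / res[r, c] + 1 / res[r2, c2]) / dist
                        oracle.add((
                            (r, c), (r2, c2), round(cond, 12),
                            round(dist * (res[r, c] + res[r2, c2]) / 2, 12),
                        ))
        got = set()
        for i, j, cond, cost in zip(g.edge_i, g.edge_j, g.conductance, g.cost):
            got.add((tuple(g.cells[i]), tuple(g.cells[j]),
                     round(cond, 12), round(cost, 12)))
        assert got == oracle

    def test_harmonic_mean_option(self):
        surf = make_surface(np.array([[1.0, 3.0]]))
        g = build_transition_graph(surf, conductance_mean="harmonic")
        np.testing.assert_allclose(g.conductance, [2.0 / 4.0])

    def test_all_nodata_rejected(self):
        mask = np.ones((2, 2), bool)
        mask[0, 0] = False
        with pytest.raises(ValueError, match="2 valid cells"):
            build_transition_graph(make_surface(np.ones((2, 2)), mask=mask))


def _manual_graph(edges, n):
    """TransitionGraph over abstract nodes for resistor-algebra checks."""
    surf = make_surface(np.ones((1, n)))
    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])
    cond = np.array([e[2] for e in edges], dtype=float)
    return TransitionGraph(
        node_of_cell=np.arange(n)[None, :],
        cells=np.column_stack([np.zeros(n, int), np.arange(n)]),
        edge_i=ei, edge_j=ej, conductance=cond, cost=1.0 / cond,
        surface=surf,
    )


class TestCommuteDistance:
    def test_single_edge_closed_form(self):
        g = _manual_graph([(0, 1, 0.5)], 2)
        C = commute_distance_matrix(g, np.array([0, 1]))
        # R_eff = 2, vol = 2 * 0.5 = 1, commute = vol * R_eff = 2
        assert C[0, 1] == pytest.approx(2.0)

    def test_series_and_parallel_resistor_algebra(self):
        series = _manual_graph([(0, 1, 1.0), (1, 2, 1.0)], 3)
        C = commute_distance_matrix(series, np.array([0, 2]))
        assert C[0, 1] / series.volume == pytest.approx(2.0)  # R_eff = 1 + 1
        parallel = _manual_graph([(0, 1, 1.0), (0, 1, 1.0)], 2)
        C = commute_distance_matrix(parallel, np.array([0, 1]))
        assert C[0, 1] / parallel.volume == pytest.approx(0.5)

    def test_matches_dense_pseudoinverse_oracle(self, rng):
        surf = random_surface(rng, 5)
        g = build_transition_graph(surf)
        sites = rng.choice(g.n_nodes, size=4, replace=False)
        C = commute_distance_matrix(g, sites)
        Lp = laplacian_pseudoinverse(g.laplacian().toarray())
        vol = g.volume
        for a, i in enumerate(sites):
            for b, j in enumerate(sites):
                expect = vol * (Lp[i, i] + Lp[j, j] - 2 * Lp[i, j])
                assert C[a, b] == pytest.approx(expect, abs=1e-8)

    def test_metric_properties(self, rng):
        surf = random_surface(rng, 6)
        g = build_transition_graph(surf)
        sites = rng.choice(g.n_nodes, size=6, replace=False)
        C = commute_distance_matrix(g, sites)
        assert np.all(C >= -1e-12)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 0.0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert C[i, j] <= C[i, k] + C[k, j] + 1e-9

    def test_uniform_resistance_rescaling(self, rng):
        # doubling every resistance doubles the effective resistance but
        # halves the graph volume, so the commute distance (expected
        # round-trip steps) is invariant — and so is the MLPE fit after
        # predictor standardization
        vals = rng.uniform(1, 3, size=(5, 5))
        g1 = build_transition_graph(make_surface(vals))
        g2 = build_transition_graph(make_surface(2 * vals))
        sites = np.array([0, 7, 19])
        C1 = commute_distance_matrix(g1, sites)
        C2 = commute_distance_matrix(g2, sites)
        np.testing.assert_allclose(C2, C1, rtol=1e-10)
        r1 = C1 / g1.volume
        r2 = C2 / g2.volume
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-10)

    def test_disconnected_sites_reported(self):
        mask = np.zeros((3, 3), bool)
        mask[:, 1] = True  # vertical cut
        surf = make_surface(np.ones((3, 3)), mask=mask)
        g = build_transition_graph(surf)
        left = g.node_at(0, 0)
        right = g.node_at(0, 2)
        with pytest.raises(ValueError, match="disconnected"):
            commute_distance_matrix(g, np.array([left, right]))


def circuit_passage_oracle(g, s, t):
    """Independent per-pair circuit throughflow: dense pseudo-inverse solve."""
    L = g.laplacian().toarray()
    Lp = laplacian_pseudoinverse(L)
    v = Lp[:, s] - Lp[:, t]
    out = np.zeros(g.n_nodes)
    for i, j, c in zip(g.edge_i, g.edge_j, g.conductance):
        cur = abs(c * (v[i] - v[j]))
        out[i] += cur
        out[j] += cur
    out[s] += 1.0
    out[t] += 1.0
    return 0.5 * out


class TestRSP:
    def test_two_node_conservation(self):
        surf = make_surface(np.array([[1.0, 1.0]]))
        g = build_transition_graph(surf)
        pm = rsp_net_passages(g, 0, 1, RSPConfig(theta=1e-6))
        np.testing.assert_allclose(pm.values.ravel(), [1.0, 1.0])

    def test_flow_conservation_at_endpoints(self, rng):
        surf = random_surface(rng, 5)
        g = build_transition_graph(surf)
        for theta in (1e-6, 0.5, 5.0):
            pm = rsp_net_passages(g, 2, 17, RSPConfig(theta=theta))
            v = pm.values[g.cells[:, 0], g.cells[:, 1]]
            assert v[2] == pytest.approx(1.0, abs=1e-9)
            assert v[17] == pytest.approx(1.0, abs=1e-9)

    def test_random_walk_limit_matches_circuit_oracle(self, rng):
        for _ in range(5):
            surf = random_surface(rng, 6)
            g = build_transition_graph(surf)
            s, t = rng.choice(g.n_nodes, size=2, replace=False)
            # force the exact RSP solve at the random-walk setting
            pm = rsp_net_passages(
                g, int(s), int(t), RSPConfig(theta=1e-6, circuit_tolerance=0.0)
            )
            v = pm.values[g.cells[:, 0], g.cells[:, 1]]
            oracle = circuit_passage_oracle(g, int(s), int(t))
            rel = np.abs(v - oracle) / np.maximum(np.abs(oracle), 1e-12)
            assert rel.max() < 1e-4

    def test_circuit_shortcut_equals_exact_rsp(self, rng):
        surf = random_surface(rng, 5)
        g = build_transition_graph(surf)
        shortcut = rsp_net_passages(g, 0, 25 - 1, RSPConfig(theta=1e-6))
        exact = rsp_net_passages(
            g, 0, 25 - 1, RSPConfig(theta=1e-6, circuit_tolerance=0.0)
        )
        np.testing.assert_allclose(shortcut.values, exact.values,
                                   rtol=1e-3, atol=1e-8)

    def test_least_cost_limit_on_identifiable_instance(self, rng):
        kept = 0
        while kept < 3:
            surf = random_surface(rng, 6, lo=1.0, hi=6.0)
            g = build_transition_graph(surf)
            s, t = 0, g.n_nodes - 1
            if not lcp_identifiable(g, s, t, margin=0.6):
                continue
            kept += 1
            pm = rsp_net_passages(g, s, t, RSPConfig(theta=12.0))
            path = least_cost_path_nodes(g, s, t)
            ind = np.zeros(g.n_nodes)
            ind[path] = 1.0
            v = pm.values[g.cells[:, 0], g.cells[:, 1]]
            assert np.abs(v - ind).max() < 0.01

    def test_entropy_interpolates_between_limits(self, rng):
        # participation (effective number of traversed cells) shrinks as
        # theta moves from the random-walk toward the least-cost limit
        surf = random_surface(rng, 6)
        g = build_transition_graph(surf)
        s, t = 0, g.n_nodes - 1
        spread = []
        for theta in (1e-6, 1.0, 4.0, 12.0):
            pm = rsp_net_passages(g, s, t, RSPConfig(theta=theta))
            v = pm.values[g.cells[:, 0], g.cells[:, 1]]
            p = v / v.sum()
            spread.append(1.0 / np.sum(p * p))
        assert all(a >= b - 1e-9 for a, b in zip(spread, spread[1:]))

    def test_theta_bounds_enforced(self):
        with pytest.raises(ValueError, match="theta"):
            RSPConfig(theta=25.0)
        with pytest.raises(ValueError, match="theta"):
            RSPConfig(theta=0.0)

    def test_same_source_target_rejected(self, rng):
        g = build_transition_graph(random_surface(rng, 3))
        with pytest.raises(ValueError, match="differ"):
            rsp_net_passages(g, 1, 1, RSPConfig(theta=1e-6))


def lcp_identifiable(g, s, t, margin):
    """True when the least-cost path is unique with route-cost slack > margin."""
    n = g.n_nodes
    A = sp.coo_matrix(
        (np.r_[g.cost, g.cost], (np.r_[g.edge_i, g.edge_j],
                                 np.r_[g.edge_j, g.edge_i])),
        shape=(n, n),
    ).tocsr()
    ds = dijkstra(A, indices=[s])[0]
    dt = dijkstra(A, indices=[t])[0]
    base = ds[t]
    path = least_cost_path_nodes(g, s, t)
    on_path = set(zip(path[:-1], path[1:])) | set(zip(path[1:], path[:-1]))
    slack = np.minimum(
        ds[g.edge_i] + g.cost + dt[g.edge_j] - base,
        ds[g.edge_j] + g.cost + dt[g.edge_i] - base,
    )
    used = np.array([
        (a, b) in on_path for a, b in zip(g.edge_i, g.edge_j)
    ])
    return bool(np.all(slack[~used] > margin) and np.all(slack[used] < 1e-9))
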