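import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from resistscape import (
    GridSpec,
    RasterGrid,
    idw_interpolate,
    mcp_buffer_extent,
    merge_host_defoliation,
    read_raster,
    resample_to_grid,
    vif_filter,
    write_raster,
)


def grid(values, cell=1.0, mask=None, name=""):
    values = np.asarray(values, dtype=float)
    nr, nc = values.shape
    spec = GridSpec(nr, nc, 0.0, nr * cell, cell)
    return RasterGrid(values, spec, mask=mask, name=name)


class TestAsciiRoundTrip:
    def test_constant_grid_roundtrip_bit_exact(self, tmp_path):
        g = grid(np.full((3, 3), 7.25), cell=5.0)
        p = tmp_path / "g.asc"
        write_raster(g, p)
        back = read_raster(p)
        np.testing.assert_array_equal(back.values, g.values)
        assert back.spec == g.spec
        assert not back.mask.any()

    def test_nodata_cells_stay_masked(self, tmp_path):
        mask = np.zeros((2, 3), bool)
        mask[0, 1] = True
        g = grid(np.arange(6.0).reshape(2, 3), mask=mask)
        p = tmp_path / "g.asc"
        write_raster(g, p)
        back = read_raster(p)
        assert back.mask[0, 1]
        np.testing.assert_array_equal(back.values[~back.mask], g.values[~g.mask])

    def test_full_precision_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        g = grid(rng.uniform(-1e6, 1e6, size=(4, 5)))
        p = tmp_path / "g.asc"
        write_raster(g, p)
        np.testing.assert_array_equal(read_raster(p).values, g.values)

    def test_unsupported_format_rejected(self, tmp_path):
        g = grid(np.ones((2, 2)))
        with pytest.raises(ValueError, match="unsupported raster format"):
            write_raster(g, tmp_path / "g.tif")
        (tmp_path / "x.tif").write_bytes(b"II*\x00")
        with pytest.raises(ValueError, match="unsupported raster format"):
            read_raster(tmp_path / "x.tif")


class TestResample:
    def test_constant_is_preserved(self):
        g = grid(np.full((8, 8), 3.5))
        target = GridSpec(2, 2, 0.0, 8.0, 4.0)
        out = resample_to_grid(g, target, "mean-aggregate")
        np.testing.assert_allclose(out.values, 3.5)
        out2 = resample_to_grid(g, GridSpec(16, 16, 0.0, 8.0, 0.5), "bilinear")
        np.testing.assert_allclose(out2.values, 3.5)

    def test_checkerboard_aggregates_to_midpoint(self):
        v = np.indices((20, 20)).sum(axis=0) % 2 * 100.0
        g = grid(v, cell=250.0)
        target = GridSpec(1, 1, 0.0, 5000.0, 5000.0)
        out = resample_to_grid(g, target, "mean-aggregate")
        np.testing.assert_allclose(out.values, 50.0)

    def test_block_mean_matches_oracle(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(4, 4))
        g = grid(v)
        out = resample_to_grid(g, GridSpec(2, 2, 0.0, 4.0, 2.0), "mean-aggregate")
        oracle = np.array([
            [v[:2, :2].mean(), v[:2, 2:].mean()],
            [v[2:, :2].mean(), v[2:, 2:].mean()],
        ])
        np.testing.assert_allclose(out.values, oracle, atol=1e-12)

    def test_mean_aggregate_conserves_spatial_mean(self):
        rng = np.random.default_rng(3)
        g = grid(rng.uniform(0, 10, size=(12, 12)))
        out = resample_to_grid(g, GridSpec(3, 3, 0.0, 12.0, 4.0), "mean-aggregate")
        assert abs(out.values.mean() - g.values.mean()) < 1e-6 * abs(g.values.mean())

    def test_disjoint_extents_rejected(self):
        g = grid(np.ones((4, 4)))
        far = GridSpec(2, 2, 100.0, 104.0, 2.0)
        with pytest.raises(ValueError, match="overlap"):
            resample_to_grid(g, far, "mean-aggregate")


class TestIDW:
    target = GridSpec(4, 4, 0.0, 4.0, 1.0)

    def test_single_station_gives_constant_field(self):
        st = pd.DataFrame({"station": ["a"], "x": [1.3], "y": [2.2], "value": [42.0]})
        out = idw_interpolate(st, self.target)
        np.testing.assert_allclose(out.values, 42.0)

    def test_equidistant_cell_takes_mean(self):
        # cell center (2.5, 2.5) equidistant from the two stations
        st = pd.DataFrame({"station": ["a", "b"], "x": [1.5, 3.5],
                           "y": [2.5, 2.5], "value": [10.0, 30.0]})
        out = idw_interpolate(st, self.target, power=2)
        r, c = self.target.cell_of(2.5, 2.5)
        assert out.values[r, c] == pytest.approx(20.0, abs=1e-12)

    def test_station_on_cell_center_is_exact(self):
        st = pd.DataFrame({"station": ["a", "b"], "x": [0.5, 3.0],
                           "y": [3.5, 1.0], "value": [5.0, 99.0]})
        out = idw_interpolate(st, self.target)
        assert out.values[0, 0] == 5.0

    def test_matches_weighted_sum_oracle(self):
        st = pd.DataFrame({
            "station": list("abc"),
            "x": [0.1, 3.9, 2.0], "y": [0.1, 0.5, 3.9],
            "value": [1.0, 5.0, -2.0],
        })
        out = idw_interpolate(st, self.target, power=2)
        qx, qy = 1.5, 2.5  # a cell center
        w = [(qx - x) ** 2 + (qy - y) ** 2 for x, y in zip(st.x, st.y)]
        w = [1.0 / d for d in w]
        oracle = sum(wi * v for wi, v in zip(w, st.value)) / sum(w)
        r, c = self.target.cell_of(qx, qy)
        assert out.values[r, c] == pytest.approx(oracle, abs=1e-10)

    def test_conflicting_duplicate_stations_rejected(self):
        st = pd.DataFrame({"station": ["a", "b"], "x": [1.0, 1.0],
                           "y": [1.0, 1.0], "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate station"):
            idw_interpolate(st, self.target)


class TestMCPExtent:
    square = pd.DataFrame({"site": list("abcd"), "x": [0, 1, 1, 0],
                           "y": [0, 0, 1, 1], "n": 1})

    def test_zero_buffer_returns_hull(self):
        poly = mcp_buffer_extent(self.square, 0.0)
        assert poly.area == pytest.approx(1.0)

    def test_buffered_area_closed_form(self):
        b = 0.3
        poly = mcp_buffer_extent(self.square, b)
        expected = 1 + 4 * b + np.pi * b * b
        assert poly.area == pytest.approx(expected, rel=1e-3)

    def test_sites_strictly_inside_buffered_hull(self):
        poly = mcp_buffer_extent(self.square, 0.1)
        for x, y in zip(self.square.x, self.square.y):
            assert poly.contains(Point(x, y))

    def test_hull_matches_gift_wrapping_oracle(self, rng):
        pts = rng.uniform(0, 10, size=(10, 2))
        sites = pd.DataFrame({"site": range(10), "x": pts[:, 0],
                              "y": pts[:, 1], "n": 1})
        poly = mcp_buffer_extent(sites, 0.0)
        hull_xy = set(map(tuple, np.round(
            np.array(poly.exterior.coords[:-1]), 9)))
        oracle = set(map(tuple, np.round(_gift_wrap(pts), 9)))
        assert hull_xy == oracle

    def test_too_few_or_collinear_sites_rejected(self):
        two = self.square.iloc[:2]
        with pytest.raises(ValueError, match="at least 3"):
            mcp_buffer_extent(two, 0.0)
        line = pd.DataFrame({"site": list("abc"), "x": [0, 1, 2],
                             "y": [0, 1, 2], "n": 1})
        with pytest.raises(ValueError, match="collinear"):
            mcp_buffer_extent(line, 0.0)


def _gift_wrap(pts: np.ndarray) -> np.ndarray:
    """Brute-force convex hull (gift wrapping); oracle only."""
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull, cur = [start], start
    while True:
        nxt = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u, v = pts[nxt] - pts[cur], pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur]) >
                             np.linalg.norm(pts[nxt] - pts[cur])):
                nxt = j
        if nxt == start:
            break
        hull.append(nxt)
        cur = nxt
    return pts[hull]


class TestHostDefoliationMerge:
    def test_simple_subtraction(self):
        out = merge_host_defoliation(grid([[60.0]]), grid([[20.0]]))
        assert out.values[0, 0] == 40.0
        assert out.name == "host_cover_net"

    def test_clipped_at_zero(self):
        out = merge_host_defoliation(grid([[10.0]]), grid([[30.0]]))
        assert out.values[0, 0] == 0.0

    def test_zero_defoliation_is_identity(self):
        host = grid(np.arange(9.0).reshape(3, 3) * 10)
        out = merge_host_defoliation(host, grid(np.zeros((3, 3))))
        np.testing.assert_array_equal(out.values, host.values)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different grids"):
            merge_host_defoliation(grid(np.ones((2, 2))), grid(np.ones((3, 3))))


class TestVIF:
    def test_orthogonal_covariates_all_kept_vif_one(self):
        n = 8
        X = np.random.default_rng(5).normal(size=(n * n, 3))
        X -= X.mean(axis=0)
        H = np.linalg.qr(X)[0]   # centered, mutually orthogonal columns
        stack = [grid(H[:, j].reshape(n, n), name=f"c{j}") for j in range(3)]
        diag = vif_filter(stack, threshold=2.5)
        assert diag.dropped == []
        assert all(abs(v - 1.0) < 1e-8 for v in diag.vif.values())

    def test_exact_collinearity_dropped_first_with_warning(self, rng):
        a = rng.normal(size=(6, 6))
        b = rng.normal(size=(6, 6))
        stack = [grid(a, name="x1"), grid(b, name="x2"), grid(a + b, name="x3")]
        with pytest.warns(UserWarning, match="collinear"):
            diag = vif_filter(stack, threshold=2.5)
        assert diag.dropped[0] == "x3"
        assert np.isinf(diag.vif["x3"])

    def test_known_correlation_gives_closed_form_vif(self, rng):
        # two predictors with sample correlation exactly 0.8:
        # VIF = 1/(1-0.64) = 2.78 > 2.5, so one is dropped
        n = 400
        a = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = rng.normal(size=n)
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal to a
        b /= b.std()
        rho = 0.8
        x2 = rho * a + np.sqrt(1 - rho * rho) * b
        stack = [grid(a.reshape(20, 20), name="x1"),
                 grid(x2.reshape(20, 20), name="x2")]
        diag = vif_filter(stack, threshold=2.5)
        assert len(diag.dropped) == 1
        expected = 1.0 / (1.0 - rho * rho)
        dropped = diag.dropped[0]
        assert diag.vif[dropped] == pytest.approx(expected, rel=1e-9)

    def test_needs_two_covariates(self):
        with pytest.raises(ValueError, match="at least 2"):
            vif_filter([grid(np.ones((2, 2)))])
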