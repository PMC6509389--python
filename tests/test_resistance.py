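import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import csc_matrix

from samplescape import (
    DistanceMatrix,
    Raster,
    SurfaceSpec,
    build_graph,
    effective_resistance,
    parameterize,
    read_ascii_grid,
    resistance_distances,
    uniform_ibd_predictor,
    vif_screen,
    write_ascii_grid,
)
from samplescape.genotypes import SiteRegistry


def dense_pinv_resistance(L, nodes):
    """Independent oracle: R(s,t) = (e_s - e_t)' L^+ (e_s - e_t)."""
    Lp = np.linalg.pinv(L.toarray(), hermitian=True)
    m = len(nodes)
    R = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            e = np.zeros(L.shape[0])
            e[nodes[a]] += 1
            e[nodes[b]] -= 1
            R[a, b] = e @ Lp @ e
    return R


class TestRasterIO:
    def test_ascii_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 3, (5, 4))
        vals[0, 0] = np.nan
        r = Raster(vals, cellsize=15.0, xllcorner=100.0, yllcorner=-5.0)
        p = tmp_path / "g.asc"
        write_ascii_grid(r, p)
        r2 = read_ascii_grid(p)
        assert np.allclose(r.values, r2.values, equal_nan=True)
        assert r2.cellsize == 15.0 and r2.xllcorner == 100.0


class TestParameterize:
    def test_uniform(self):
        r = parameterize(Raster(np.arange(6.0).reshape(2, 3)),
                         SurfaceSpec("d", "uniform"))
        assert (r.values == 1).all()

    def test_binary_cover_fraction(self):
        rng = np.random.default_rng(1)
        cover = Raster((rng.random((20, 20)) < 0.3).astype(float))
        r = parameterize(cover, SurfaceSpec("c", "binary_cover", 1.0))
        assert set(np.unique(r.values)) == {1.0, 2.0}
        assert (r.values == 2).mean() == (cover.values == 1).mean()

    def test_binary_missing_class_error(self):
        with pytest.raises(ValueError, match="absent"):
            parameterize(Raster(np.zeros((3, 3))),
                         SurfaceSpec("c", "binary_cover", 5.0))

    def test_raw_min_shift_positive(self):
        r = parameterize(Raster(np.array([[0.0, 2.0], [-1.0, 3.0]])),
                         SurfaceSpec("s", "raw"))
        assert r.values.min() > 0


class TestBuildGraph:
    def test_unit_path_conductances(self):
        L, ci = build_graph(Raster(np.ones((1, 3))), connectivity=4)
        A = L.toarray()
        assert A[ci[0, 0], ci[0, 1]] == pytest.approx(-1.0)
        assert A[ci[0, 1], ci[0, 2]] == pytest.approx(-1.0)
        assert np.abs(A.sum(axis=1)).max() < 1e-12

    def test_average_resistance_rule(self):
        L, ci = build_graph(Raster(np.array([[1.0, 3.0]])), connectivity=4)
        assert L.toarray()[ci[0, 0], ci[0, 1]] == pytest.approx(-0.5)

    def test_diagonal_scaled_by_sqrt2(self):
        L, ci = build_graph(Raster(np.ones((2, 2))), connectivity=8)
        A = L.toarray()
        assert A[ci[0, 0], ci[1, 1]] == pytest.approx(-1 / np.sqrt(2))
        assert A[ci[0, 0], ci[0, 1]] == pytest.approx(-1.0)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            build_graph(Raster(np.array([[1.0, 0.0]])), 4)


class TestEffectiveResistance:
    def test_series_circuit(self):
        L, ci = build_graph(Raster(np.ones((1, 3))), connectivity=4)
        R = effective_resistance(L, [ci[0, 0], ci[0, 2]])
        assert R[0, 1] == pytest.approx(2.0)

    def test_triangle_circuit(self):
        # three pairwise unit resistors: R = (1 * 2) / 3 between any pair
        i = [0, 1, 0, 2, 1, 2, 0, 1, 2]
        j = [1, 0, 2, 0, 2, 1, 0, 1, 2]
        v = [-1, -1, -1, -1, -1, -1, 2, 2, 2]
        L = csc_matrix((v, (i, j)), shape=(3, 3), dtype=float)
        R = effective_resistance(L, [0, 1, 2])
        off = R[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 2 / 3)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_dense_pseudoinverse(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 10)), int(rng.integers(2, 10)))
        rast = Raster(rng.uniform(0.2, 5.0, shape))
        conn = int(rng.choice([4, 8]))
        L, ci = build_graph(rast, conn)
        flat = ci[ci >= 0]
        nodes = rng.choice(flat, size=min(4, flat.size), replace=False)
        R = effective_resistance(L, nodes)
        assert np.abs(R - dense_pinv_resistance(L, nodes)).max() < 1e-8

    def test_metric_triangle_inequality(self):
        rng = np.random.default_rng(12)
        rast = Raster(rng.uniform(0.5, 4.0, (10, 10)))
        L, ci = build_graph(rast, 8)
        nodes = [ci[0, 0], ci[5, 5], ci[9, 9], ci[0, 9], ci[9, 0]]
        R = effective_resistance(L, nodes)
        assert np.allclose(R, R.T) and np.allclose(np.diag(R), 0)
        m = len(nodes)
        for a in range(m):
            for b in range(m):
                for c in range(m):
                    assert R[a, b] <= R[a, c] + R[c, b] + 1e-10

    def test_rayleigh_monotonicity(self):
        """Raising any cell's resistance never lowers any pairwise R."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            vals = rng.uniform(0.5, 3.0, (6, 6))
            rast = Raster(vals)
            L, ci = build_graph(rast, 8)
            nodes = [ci[0, 0], ci[5, 5], ci[0, 5]]
            R0 = effective_resistance(L, nodes)
            r, c = rng.integers(0, 6, 2)
            bumped = vals.copy()
            bumped[r, c] *= 1 + rng.uniform(0.5, 3.0)
            L2, _ = build_graph(Raster(bumped), 8)
            R1 = effective_resistance(L2, nodes)
            assert (R1 - R0).min() > -1e-10

    def test_disconnected_landscape_error(self):
        vals = np.ones((3, 3))
        vals[:, 1] = np.nan  # wall of nodata splits the raster
        rast = Raster(vals)
        L, ci = build_graph(rast, 4)
        with pytest.raises(ValueError, match="disconnected"):
            effective_resistance(L, [ci[0, 0], ci[0, 2]])


class TestUniformIBD:
    def test_strip_proportional_to_separation(self):
        rast = Raster(np.ones((1, 9)))
        reg = SiteRegistry({"a": (0, 0), "b": (0, 4), "c": (0, 8)})
        dm = uniform_ibd_predictor(rast, reg, connectivity=4)
        assert dm.loc("a", "b") == pytest.approx(4.0)
        assert dm.loc("a", "c") == pytest.approx(8.0)

    def test_equals_uniform_parameterization(self):
        rng = np.random.default_rng(2)
        cover = Raster(rng.integers(0, 3, (8, 8)).astype(float))
        reg = SiteRegistry({"a": (0, 0), "b": (7, 7), "c": (0, 7)})
        direct = uniform_ibd_predictor(cover, reg)
        via = resistance_distances(
            parameterize(cover, SurfaceSpec("u", "uniform")), reg,
            metric="uniform_ibd",
        )
        assert np.allclose(direct.values, via.values)

    def test_refinement_preserves_rank_order(self):
        """Doubling resolution of the same geometry keeps pair ordering."""
        reg1 = SiteRegistry({"a": (1, 1), "b": (1, 6), "c": (6, 6)})
        reg2 = SiteRegistry({"a": (2, 2), "b": (2, 12), "c": (12, 12)})
        d1 = uniform_ibd_predictor(Raster(np.ones((8, 8))), reg1)
        d2 = uniform_ibd_predictor(Raster(np.ones((16, 16))), reg2)
        v1, v2 = d1.condensed(), d2.condensed()
        assert (np.argsort(v1) == np.argsort(v2)).all()


def dm_from_vec(vec, labels):
    n = len(labels)
    m = np.zeros((n, n))
    m[np.tril_indices(n, -1)] = vec
    return DistanceMatrix(labels, m + m.T, "effective_resistance",
                          "population")


class TestVIF:
    labels = list("abcde")  # 10 pairs

    def test_orthogonal_predictors_untouched(self):
        # Helmert-style contrasts: zero-mean, mutually orthogonal
        H = np.array([
            [1, -1, 0, 0, 0, 0, 0, 0, 0, 0],
            [1, 1, -2, 0, 0, 0, 0, 0, 0, 0],
            [1, 1, 1, -3, 0, 0, 0, 0, 0, 0],
        ], dtype=float)
        preds = {f"p{k}": dm_from_vec(H[k], self.labels) for k in range(3)}
        kept, removed = vif_screen(preds, threshold=4.0)
        assert removed == [] and len(kept) == 3

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        x = (x - x.mean()) / x.std()
        e = rng.standard_normal(10)
        e -= e @ x / (x @ x) * x  # orthogonalize
        y = 0.9 * x + np.sqrt(1 - 0.81) * (e - e.mean()) / e.std()
        preds = {"x": dm_from_vec(x, self.labels),
                 "y": dm_from_vec(y, self.labels)}
        from samplescape.resistance import vif_table
        vifs = vif_table(preds)
        assert vifs["x"] == pytest.approx(1 / (1 - 0.81), rel=1e-6)
        kept, removed = vif_screen(preds, threshold=4.0)
        assert len(removed) == 1 and len(kept) == 1

    def test_duplicate_removed_first(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        z = rng.standard_normal(10)
        preds = {"x": dm_from_vec(x, self.labels),
                 "x_copy": dm_from_vec(x, self.labels),
                 "z": dm_from_vec(z, self.labels)}
        kept, removed = vif_screen(preds, threshold=4.0)
        assert "z" in kept
        assert {removed[0][0]} < {"x", "x_copy"}
        assert removed[0][1] == np.inf
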