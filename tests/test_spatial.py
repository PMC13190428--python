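"""Spatial weights, Moran/Gi* against brute-force oracles, (M)GWR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corridorpa.spatial import (LocalCoefficients, aggregate_blocks,
                                build_weights, getis_ord_gstar, gwr_fit,
                                mgwr_fit, morans_i, select_bandwidth)
from corridorpa.synthetic import CorridorConfig, GridStudy, generate_corridor


def grid_of(nx, ny):
    n = nx * ny
    factors = pd.DataFrame({"f": np.zeros(n)},
                           index=pd.Index(range(n), name="unit_id"))
    return GridStudy(cell_size=1000.0, nx=nx, ny=ny, origin=(0.0, 0.0),
                     factors=factors, dimension_of={"f": "service"})


def brute_force_moran(values, W):
    """Direct evaluation of the Moran double sum."""
    z = values - values.mean()
    n = len(z)
    Wd = W.matrix.toarray()
    num = sum(Wd[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / Wd.sum() * num / (z @ z)


def brute_force_gstar(values, W):
    """Direct per-unit evaluation of the Gi* formula with self-weight."""
    x = np.asarray(values, float)
    n = len(x)
    B = (W.matrix.toarray() != 0).astype(float) + np.eye(n)
    xbar, S = x.mean(), np.sqrt((x**2).mean() - x.mean()**2)
    out = np.empty(n)
    for i in range(n):
        wi = B[i]
        num = wi @ x - xbar * wi.sum()
        den = S * np.sqrt((n * (wi**2).sum() - wi.sum()**2) / (n - 1))
        out[i] = num / den
    return out


class TestWeights:
    def test_queen_and_rook_neighbor_counts(self):
        g = grid_of(3, 3)
        q = build_weights(grid=g, scheme="queen", row_standardize=False)
        r = build_weights(grid=g, scheme="rook", row_standardize=False)
        center = 4  # middle of the 3x3
        assert q.matrix[center].nnz == 8
        assert r.matrix[center].nnz == 4
        assert q.matrix.diagonal().sum() == 0

    def test_row_standardized_rows_sum_to_one(self):
        g = grid_of(5, 4)
        W = build_weights(grid=g, scheme="queen", row_standardize=True)
        sums = np.asarray(W.matrix.sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_knn_rows_have_exactly_k(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (100, 2))
        W = build_weights(points=pts, scheme="knn", k=4,
                          row_standardize=False)
        counts = np.diff(W.matrix.indptr)
        assert (counts == 4).all()

    def test_contiguity_is_symmetric(self):
        g = grid_of(4, 3)
        W = build_weights(grid=g, scheme="rook", row_standardize=False)
        assert (W.matrix != W.matrix.T).nnz == 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_weights(points=np.zeros((5, 2)), scheme="knn", k=5)
        with pytest.raises(ValueError):
            build_weights(grid=grid_of(2, 2), scheme="hexagon")


class TestMoran:
    def test_checkerboard_is_perfect_dispersion(self):
        g = grid_of(2, 2)
        W = build_weights(grid=g, scheme="rook", row_standardize=True)
        res = morans_i(np.array([1.0, -1.0, -1.0, 1.0]), W,
                       permutations=99, seed=0)
        assert res.I == pytest.approx(-1.0)
        assert res.expected == pytest.approx(-1.0 / 3.0)

    def test_matches_brute_force_double_sum(self):
        """Formula oracle on random instances up to n = 50."""
        rng = np.random.default_rng(1)
        for nx, ny in [(5, 1), (5, 2), (7, 7), (10, 5)]:
            g = grid_of(nx, ny)
            W = build_weights(grid=g, scheme="rook", row_standardize=True)
            v = rng.standard_normal(nx * ny)
            res = morans_i(v, W, permutations=9, seed=0)
            assert res.I == pytest.approx(brute_force_moran(v, W), abs=1e-12)

    def test_linear_gradient_on_chain(self):
        g = grid_of(5, 1)
        W = build_weights(grid=g, scheme="rook", row_standardize=True)
        v = np.arange(5.0)
        res = morans_i(v, W, permutations=9, seed=0)
        assert res.I == pytest.approx(brute_force_moran(v, W), abs=1e-12)
        assert res.I > 0

    def test_permutation_p_uniform_under_null(self):
        """KS check: two-sided permutation p-values of iid data are
        approximately uniform over 200 replicates."""
        g = grid_of(7, 7)
        W = build_weights(grid=g, scheme="queen")
        rng = np.random.default_rng(2)
        pvals = []
        for rep in range(200):
            v = rng.standard_normal(49)
            pvals.append(morans_i(v, W, permutations=199, seed=rep).p_two_sided)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_values_rejected(self):
        g = grid_of(3, 3)
        W = build_weights(grid=g, scheme="rook")
        with pytest.raises(ValueError):
            morans_i(np.ones(9), W)


class TestGetisOrd:
    def test_hot_block_peaks_at_center(self):
        g = grid_of(9, 9)
        W = build_weights(grid=g, scheme="queen", row_standardize=False)
        v = np.zeros(81)
        ids = np.arange(81)
        r, c = ids // 9, ids % 9
        block = (r >= 3) & (r <= 5) & (c >= 3) & (c <= 5)
        v[block] = 1.0
        z = getis_ord_gstar(v, W)
        assert np.argmax(z) == 4 * 9 + 4

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(3)
        g = grid_of(6, 5)
        W = build_weights(grid=g, scheme="queen", row_standardize=False)
        v = rng.standard_normal(30)
        np.testing.assert_allclose(getis_ord_gstar(v, W),
                                   brute_force_gstar(v, W), atol=1e-10)

    def test_shuffling_destroys_the_hotspot(self):
        g = grid_of(9, 9)
        W = build_weights(grid=g, scheme="queen", row_standardize=False)
        v = np.zeros(81)
        v[[30, 31, 32, 39, 40, 41, 48, 49, 50]] = 1.0
        clustered_max = np.abs(getis_ord_gstar(v, W)).max()
        rng = np.random.default_rng(4)
        weaker = sum(np.abs(getis_ord_gstar(rng.permutation(v), W)).max()
                     < clustered_max for _ in range(30))
        assert weaker >= 27

    def test_symmetric_under_rotation(self):
        g = grid_of(8, 6)
        rng = np.random.default_rng(5)
        v = rng.standard_normal(48)
        W = build_weights(grid=g, scheme="queen", row_standardize=False)
        z = getis_ord_gstar(v, W)
        # 180-degree rotation of the field permutes the z map identically
        rot = v.reshape(6, 8)[::-1, ::-1].ravel()
        z_rot = getis_ord_gstar(rot, W)
        np.testing.assert_allclose(z_rot, z.reshape(6, 8)[::-1, ::-1].ravel(),
                                   atol=1e-12)


def planted_gwr_data(n, seed, local=True, noise=0.2):
    """Intercept + one covariate whose coefficient drifts east-west."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 1000, (n, 2))
    x1 = rng.standard_normal(n)
    beta1 = 1.0 + coords[:, 0] / 1000.0 if local else np.full(n, 1.5)
    y = 0.5 + beta1 * x1 + noise * rng.standard_normal(n)
    X = pd.DataFrame({"intercept": np.ones(n), "x1": x1})
    return X, y, coords, beta1


class TestGWR:
    def test_uniform_kernel_full_bandwidth_equals_ols(self):
        X, y, coords, _ = planted_gwr_data(120, seed=6, local=False)
        fit = gwr_fit(X, y, coords, bandwidth=120, kernel="uniform")
        ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta.to_numpy(),
                                   np.tile(ols, (120, 1)), atol=1e-8)

    def test_zero_noise_global_truth_interpolated(self):
        X, y, coords, _ = planted_gwr_data(100, seed=7, local=False, noise=0.0)
        fit = gwr_fit(X, y, coords, bandwidth=40)
        assert np.abs(fit.residuals).max() < 1e-6

    def test_local_coefficient_recovery(self):
        """RMSE of the drifting coefficient surface stays below 0.15."""
        errs = []
        for seed in range(3):
            X, y, coords, beta1 = planted_gwr_data(400, seed=seed)
            bw, _ = select_bandwidth(X, y, coords)
            fit = gwr_fit(X, y, coords, bandwidth=bw)
            errs.append(np.sqrt(np.mean((fit.beta["x1"].to_numpy() - beta1)**2)))
        assert np.mean(errs) <= 0.15

    def test_bandwidth_within_bounds_and_regime_detection(self):
        X, y, coords, _ = planted_gwr_data(300, seed=8, local=False)
        bw, trace = select_bandwidth(X, y, coords, bounds=(20, 300))
        assert 20 <= bw <= 300
        assert bw >= 0.8 * 300       # global truth -> near-global bandwidth
        Xl, yl, cl, _ = planted_gwr_data(300, seed=8, local=True, noise=0.1)
        bwl, _ = select_bandwidth(Xl, yl, cl, bounds=(20, 300))
        assert bwl <= 0.5 * 300      # drifting truth -> markedly local

    def test_inverted_bounds_rejected(self):
        X, y, coords, _ = planted_gwr_data(60, seed=9)
        with pytest.raises(ValueError):
            select_bandwidth(X, y, coords, bounds=(50, 20))

    def test_small_bandwidth_rejected(self):
        X, y, coords, _ = planted_gwr_data(60, seed=10)
        with pytest.raises(ValueError):
            gwr_fit(X, y, coords, bandwidth=2)


def planted_mgwr_data(n, seed, noise=0.15):
    """One global (constant) and one local (drifting) coefficient."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 1000, (n, 2))
    xg = rng.standard_normal(n)
    xl = rng.standard_normal(n)
    beta_l = np.sin(2 * np.pi * coords[:, 0] / 1000.0)
    y = 1.0 + 1.5 * xg + beta_l * xl + noise * rng.standard_normal(n)
    X = pd.DataFrame({"intercept": np.ones(n), "x_global": xg,
                      "x_local": xl})
    return X, y, coords


class TestMGWR:
    def test_bandwidths_separate_global_from_local(self):
        X, y, coords = planted_mgwr_data(300, seed=11)
        fit = mgwr_fit(X, y, coords)
        assert fit.bandwidth["x_global"] >= 0.8 * 300
        assert fit.bandwidth["x_local"] <= 0.3 * 300

    def test_all_global_truth_matches_ols_fit(self):
        n = 200
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 1000, (n, 2))
        X = pd.DataFrame({"intercept": np.ones(n),
                          "a": rng.standard_normal(n),
                          "b": rng.standard_normal(n)})
        y = 2.0 + 1.0 * X["a"].to_numpy() - 0.5 * X["b"].to_numpy() \
            + 0.1 * rng.standard_normal(n)
        fit = mgwr_fit(X, y, coords)
        # compare fitted values on the internally z-scored target scale
        yz = (y - y.mean()) / y.std()
        Z = X.copy()
        for c in ("a", "b"):
            Z[c] = (Z[c] - Z[c].mean()) / Z[c].std(ddof=0)
        ols_fit = Z.to_numpy() @ np.linalg.lstsq(Z.to_numpy(), yz, rcond=None)[0]
        rms = np.sqrt(np.mean((fit.fitted - ols_fit)**2))
        assert rms <= 0.05

    def test_rss_monotone_across_sweeps(self):
        """Backfitting RSS is non-increasing per sweep, up to the <=1%
        slack the smoothest-within-2-AICc bandwidth tie-break may trade
        away for parsimony."""
        X, y, coords = planted_mgwr_data(200, seed=13)
        fit = mgwr_fit(X, y, coords)
        rss = np.array(fit.rss_history)
        assert (np.diff(rss) <= 0.01 * rss[:-1]).all()

    def test_loosening_tol_never_needs_more_sweeps(self):
        X, y, coords = planted_mgwr_data(150, seed=14)
        tight = mgwr_fit(X, y, coords, tol=1e-5)
        loose = mgwr_fit(X, y, coords, tol=1e-4)
        assert loose.iterations <= tight.iterations

    def test_too_few_units_rejected(self):
        X, y, coords = planted_mgwr_data(40, seed=15)
        with pytest.raises(ValueError):
            mgwr_fit(X, y, coords)


class TestAggregation:
    def test_county_blocks_average_cell_values(self):
        cfg = CorridorConfig(cell_size=2500.0, seed=1,
                             factor_counts={d: 1 for d in
                                            ("service", "living", "ecology",
                                             "built_env", "socioeconomic")},
                             redundant_counts={d: 0 for d in
                                               ("service", "living", "ecology",
                                                "built_env", "socioeconomic")})
        grid, _ = generate_corridor(cfg)
        coords, agg = aggregate_blocks(grid, {"X": grid.factors}, block=4)
        assert len(coords) == len(agg["X"])
        # first county = mean of the cells in the top-left 4x4 block
        r, c = grid.rows_cols()
        members = grid.factors[(r // 4 == 0) & (c // 4 == 0)]
        np.testing.assert_allclose(agg["X"].iloc[0].to_numpy(),
                                   members.mean().to_numpy())
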