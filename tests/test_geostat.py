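import json

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, special

from geoqual.geostat import (CORRELATION_AT_RANGE, BinomialGeostatModel,
                             MaternParams, PriorSpec, great_circle_distance,
                             krige_impute, matern_cov, matern_correlation,
                             pairwise_distances, pc_prior_calibrate,
                             pc_range_calibrate, sample_pc_range_prior,
                             sample_pc_sd_prior)

from _oracles import quadrature_posterior_p


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_distance([12.0, -5.0], [12.0, -5.0]) == 0.0

    def test_antipodal_half_circumference(self):
        d = great_circle_distance([0.0, 0.0], [180.0, 0.0])
        assert d == pytest.approx(np.pi * 6371.0, rel=1e-6)  # 20015.09 km

    def test_one_degree_on_equator(self):
        d = great_circle_distance([0.0, 0.0], [1.0, 0.0])
        assert d == pytest.approx(np.pi / 180 * 6371.0, rel=1e-6)  # 111.19 km

    def test_symmetry(self):
        a, b = [10.0, 20.0], [-40.0, 55.0]
        assert great_circle_distance(a, b) == pytest.approx(
            great_circle_distance(b, a))

    def test_out_of_range_latitude_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance([0.0, 95.0], [0.0, 0.0])


class TestMatern:
    def test_zero_distance_gives_marginal_variance(self):
        p = MaternParams(2.5, 60.0)
        assert matern_cov(0.0, p) == pytest.approx(2.5)

    def test_strictly_decreasing(self):
        p = MaternParams(1.0, 60.0)
        d = np.linspace(0.0, 400.0, 100)
        c = matern_cov(d, p)
        assert (np.diff(c) < 0).all()

    def test_correlation_at_range(self):
        assert matern_correlation(60.0, 60.0) == pytest.approx(
            np.sqrt(8) * special.k1(np.sqrt(8)))
        assert 0.13 < CORRELATION_AT_RANGE < 0.15

    def test_kappa_range_identity(self):
        p = MaternParams(1.0, 37.0)
        assert p.kappa * p.range_km == pytest.approx(np.sqrt(8.0))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            matern_cov(np.array([-1.0]), MaternParams(1.0, 10.0))

    def test_covariance_plus_nugget_is_positive_definite(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 200, size=(40, 2))
        D = pairwise_distances(coords)
        C = matern_cov(D, MaternParams(1.3, 80.0)) + 0.05 * np.eye(40)
        linalg.cholesky(C)  # raises if not PD


class TestPcPriors:
    def test_log_cancellation(self):
        assert pc_prior_calibrate(3.0, np.exp(-3.0)) == pytest.approx(1.0)

    def test_stated_rate(self):
        assert pc_prior_calibrate(3.0, 0.01) == pytest.approx(-np.log(0.01) / 3)
        assert pc_prior_calibrate(3.0, 0.01) == pytest.approx(1.5351, abs=1e-4)

    def test_monte_carlo_tail_masses(self):
        rng = np.random.default_rng(1)
        n = 10 ** 5
        lam = pc_prior_calibrate(3.0, 0.01)
        sig = sample_pc_sd_prior(lam, n, rng)
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs((sig > 3.0).mean() - 0.01) < 3 * se
        lam_r = pc_range_calibrate(25.0, 0.01)
        r = sample_pc_range_prior(lam_r, n, rng)
        assert abs((r < 25.0).mean() - 0.01) < 3 * se

    def test_degenerate_alpha_rejected(self):
        with pytest.raises(ValueError):
            pc_prior_calibrate(3.0, 0.0)
        with pytest.raises(ValueError):
            pc_range_calibrate(10.0, 1.0)

    def test_default_r0_is_five_percent_of_region_size(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [40.0, 30.0]])
        r0 = PriorSpec().resolve_r0(coords, "planar_km")
        assert r0 == pytest.approx(5.0)


class TestFit:
    def test_glm_oracle_intercept_only(self):
        rng = np.random.default_rng(0)
        n = 20
        m = np.full(n, 200)
        y = rng.binomial(m, 0.3)
        mod = BinomialGeostatModel(y, m, np.ones((n, 1)),
                                   rng.uniform(0, 100, (n, 2)))
        res = mod.fit(seed=1, n_draws=500,
                      fixed_hypers={"sigma2": 0.0, "range_km": 1.0,
                                    "sigma2_eps": 0.0})
        pooled = y.sum() / m.sum()
        assert np.abs(res.fitted_p - pooled).max() < 0.01

    def test_quadrature_oracle_three_clusters(self, data_dir):
        df = pd.read_csv(data_dir / "synthetic_oracle_clusters.csv")
        hyp = {"sigma2": 1.0, "range_km": 40.0, "sigma2_eps": 0.1}
        offset = -1.0
        mean, sd = quadrature_posterior_p(
            df["y"], df["m"], df[["x_km", "y_km"]], offset=offset, **hyp)
        mod = BinomialGeostatModel(df["y"], df["m"], None,
                                   df[["x_km", "y_km"]], offset=offset)
        res = mod.fit(seed=5, n_draws=4000, fixed_hypers=hyp)
        assert res.method == "mh"
        assert np.abs(res.fitted_p - mean).max() < 0.01
        post_sd = res.fitted_p_draws.std(0, ddof=1)
        assert np.abs(post_sd / sd - 1).max() < 0.10

    def test_posterior_summary_and_interval_shapes(self, medium_counts):
        mod = BinomialGeostatModel.from_cluster_counts(
            medium_counts.clusters, ["cov_0"])
        res = mod.fit(seed=3, n_draws=200, n_mcmc=120, n_burn=60)
        assert res.beta_draws.shape == (200, 2)
        assert ((res.fitted_p > 0) & (res.fitted_p < 1)).all()
        ci = res.beta_interval()
        assert (ci[:, 0] < ci[:, 1]).all()
        assert "sigma2" in res.summary()

    def test_input_validation(self):
        with pytest.raises(ValueError, match="m >= 1"):
            BinomialGeostatModel([0], [0], None, [[0.0, 0.0]])
        with pytest.raises(ValueError, match="y <= m"):
            BinomialGeostatModel([5], [3], None, [[0.0, 0.0]])


class TestPredict:
    @pytest.fixture(scope="class")
    def fit_and_grid(self, medium_counts):
        sv = medium_counts
        mod = BinomialGeostatModel.from_cluster_counts(sv.clusters, ["cov_0"])
        res = mod.fit(seed=7, n_draws=250, n_mcmc=150, n_burn=70)
        return sv, res

    def test_surface_has_requested_draw_count(self, fit_and_grid):
        sv, res = fit_and_grid
        coords = sv.region.cell_coords()[:25]
        X = np.column_stack([np.ones(25), np.zeros(25)])
        surf = res.predict(coords, X, n_samples=1000, seed=1)
        assert surf.draws.shape == (1000, 25)
        assert ((surf.draws > 0) & (surf.draws < 1)).all()
        assert (surf.sd >= 0).all()

    def test_no_spatial_effect_reduces_to_logistic_prediction(self):
        rng = np.random.default_rng(2)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([0.3, -0.5])
        m = np.full(n, 400)
        y = rng.binomial(m, special.expit(X @ beta))
        mod = BinomialGeostatModel(y, m, X, rng.uniform(0, 50, (n, 2)))
        res = mod.fit(seed=1, n_draws=400,
                      fixed_hypers={"sigma2": 0.0, "range_km": 1.0,
                                    "sigma2_eps": 0.0})
        Xg = np.array([[1.0, 0.7], [1.0, -1.2]])
        surf = res.predict(np.array([[5.0, 5.0], [40.0, 20.0]]), Xg,
                           n_samples=400, seed=0)
        bhat = res.beta_draws.mean(0)
        assert np.abs(surf.mean - special.expit(Xg @ bhat)).max() < 0.01

    def test_prediction_consistency_at_data_locations(self, fit_and_grid):
        # predicting at the data locations with the nugget added back should
        # statistically reproduce the fitted probabilities
        sv, res = fit_and_grid
        mod = res.model
        surf = res.predict(mod.coords, mod.X, n_samples=res.n_draws,
                           include_nugget=True, seed=3)
        assert np.mean(np.abs(surf.mean - res.fitted_p)) < 0.02

    def test_shrinkage_toward_observed_at_precise_cluster(self):
        # one cluster with huge m and tiny nugget: surface at that location
        # must sit close to its observed proportion
        rng = np.random.default_rng(8)
        n = 40
        coords = rng.uniform(0, 100, (n, 2))
        m = np.full(n, 30)
        m[0] = 5000
        p_true = special.expit(rng.normal(-1.0, 0.8, size=n))
        y = rng.binomial(m, p_true)
        mod = BinomialGeostatModel(y, m, np.ones((n, 1)), coords)
        res = mod.fit(seed=2, n_draws=300,
                      fixed_hypers={"sigma2": 1.0, "range_km": 30.0,
                                    "sigma2_eps": 1e-4})
        surf = res.predict(coords[:1], np.ones((1, 1)), n_samples=300, seed=1)
        assert abs(surf.mean[0] - y[0] / m[0]) < 0.02

    def test_misaligned_covariates_rejected(self, fit_and_grid):
        sv, res = fit_and_grid
        with pytest.raises(ValueError, match="aligned|transform"):
            res.predict(np.zeros((3, 2)), np.ones((3, 5)))
        with pytest.raises(ValueError, match="imput"):
            res.predict(np.zeros((1, 2)), np.array([[1.0, np.nan]]))


class TestKriging:
    def test_exact_at_known_locations(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (12, 2))
        vals = np.sin(pts[:, 0] / 20) + pts[:, 1] / 50
        out = krige_impute(pts, vals, pts[[3, 7]])
        assert np.allclose(out, vals[[3, 7]], atol=1e-6)

    def test_constant_field_imputes_constant(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (8, 2))
        out = krige_impute(pts, np.full(8, 4.2), [[10.0, 10.0], [90.0, 50.0]])
        assert np.allclose(out, 4.2)

    def test_symmetric_midpoint_is_arithmetic_mean(self):
        # two symmetric data pairs; query equidistant from the inner pair
        pts = np.array([[0.0, 0.0], [40.0, 0.0], [-30.0, 0.0], [70.0, 0.0]])
        vals = np.array([1.0, 3.0, 1.0, 3.0])
        out = krige_impute(pts, vals, [[20.0, 0.0]])
        assert out[0] == pytest.approx(2.0, abs=1e-8)

    def test_coincident_points_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            krige_impute(pts, [1.0, 2.0, 3.0], [[0.5, 0.5]])
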