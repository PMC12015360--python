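import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geoqual.exploratory import (empirical_logit, empirical_variogram,
                                 lattice_adjacency, log_standardize,
                                 apply_log_standardize, morans_i,
                                 queen_adjacency, vif)
from geoqual.synthetic_data import SimulationConfig, make_region, simulate_latent_field

from _oracles import morans_i_bruteforce


class TestEmpiricalLogit:
    @pytest.mark.parametrize("y, m, expected", [
        (5, 10, 0.0),
        (0, 9, np.log(0.5 / 9.5)),          # approx -2.9444
        (7, 7, np.log(7.5 / 0.5)),
    ])
    def test_values(self, y, m, expected):
        assert empirical_logit(y, m) == pytest.approx(expected)

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            empirical_logit(0, 0)

    @given(m=st.integers(1, 500), y=st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_finiteness(self, m, y):
        y = min(y, m)
        v = empirical_logit(y, m)
        assert np.isfinite(v)
        assert v == pytest.approx(-empirical_logit(m - y, m))


class TestLogStandardize:
    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=50)
        a, _ = log_standardize(pd.DataFrame({"v": x}))
        b, _ = log_standardize(pd.DataFrame({"v": 7.3 * x}))
        assert np.allclose(a["v"], b["v"])

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.lognormal(size=200),
                           "b": rng.lognormal(2, 1, size=200)})
        out, _ = log_standardize(df)
        assert np.allclose(out.mean(), 0.0, atol=1e-10)
        assert np.allclose(out.var(ddof=0), 1.0, atol=1e-10)

    def test_stored_parameters_reproduce_training_output(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.lognormal(size=50)})
        out, params = log_standardize(df)
        again = apply_log_standardize(df, params)
        assert np.allclose(out["a"], again["a"])

    def test_zero_column_gets_offset(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0, 5.0]})
        out, params = log_standardize(df)
        assert params.offsets["a"] == 0.5  # half the smallest positive value
        assert np.isfinite(out["a"]).all()

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            log_standardize(pd.DataFrame({"a": [2.0, 2.0, 2.0]}))


class TestVif:
    def test_orthogonal_columns_give_unity(self):
        n = 16
        t = np.arange(n)
        df = pd.DataFrame({"a": np.where(t % 2 == 0, 1.0, -1.0),
                           "b": np.where(t % 4 < 2, 1.0, -1.0),
                           "c": np.where(t % 8 < 4, 1.0, -1.0)})
        out = vif(df)
        assert np.allclose(out["vif"], 1.0)
        assert not out["flagged"].any()

    def test_duplicate_column_flagged_not_crashed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        out = vif(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)}))
        assert np.isinf(out.loc["a", "vif"]) and out.loc["a", "flagged"]

    def test_near_linear_dependence_exceeds_threshold(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=200)
        x2 = rng.normal(size=200)
        x3 = x1 + x2 + rng.normal(scale=0.05, size=200)
        out = vif(pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}))
        # independent verification from the R^2 definition
        import statsmodels.api as sm

        r2 = sm.OLS(x3, sm.add_constant(np.column_stack([x1, x2]))).fit().rsquared
        assert out.loc["x3", "vif"] == pytest.approx(1 / (1 - r2), rel=1e-6)
        assert out.loc["x3", "vif"] > 4.0

    def test_vif_at_least_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        assert (vif(df)["vif"] >= 1.0).all()


class TestVariogram:
    def test_two_points_single_pair(self):
        vg = empirical_variogram([1.0, 4.0], [[0, 0], [10, 0]], n_bins=1)
        assert vg.semivariance[vg.pair_counts > 0][0] == pytest.approx((3.0 ** 2) / 2)

    def test_iid_noise_is_flat(self):
        # per-bin standard errors come from replicate simulations because
        # Matheron bins share points and are not independent pairs
        rng = np.random.default_rng(3)
        n = 150
        coords = rng.uniform(0, 100, size=(n, 2))
        reps = np.array([empirical_variogram(rng.normal(size=n), coords,
                                             n_bins=8).semivariance
                         for _ in range(40)])
        se = reps.std(axis=0, ddof=1)
        vg = empirical_variogram(np.random.default_rng(99).normal(size=n),
                                 coords, n_bins=8)
        ok = vg.pair_counts > 30
        assert (np.abs(vg.semivariance[ok] - 1.0) < 3 * se[ok]).all()

    def test_spatial_field_variogram_rises_to_sill(self):
        cfg = SimulationConfig(seed=5, n_clusters=10, grid_shape=(14, 14),
                               n_districts=1, cell_km=5.0)
        region = make_region(cfg)
        sims = [simulate_latent_field(region, 1.0, 20.0, seed=s).omega
                for s in range(30)]
        coords = region.cell_coords()
        gammas = np.mean([empirical_variogram(z, coords, n_bins=6).semivariance
                          for z in sims], axis=0)
        assert gammas[0] < 0.5          # strong short-range correlation
        assert gammas[-1] > 0.75        # levels off near the sill sigma2 = 1

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            empirical_variogram([1.0, 2.0], [[0, 0], [0, 0]])


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        W = lattice_adjacency(4, 4, rook=True)
        z = (np.indices((4, 4)).sum(0) % 2).ravel().astype(float)
        rep = morans_i(z, W, seed=0)
        assert rep["I"] == pytest.approx(-1.0)
        Wr = W / W.sum(1, keepdims=True)
        assert morans_i_bruteforce(z, Wr) == pytest.approx(-1.0)

    def test_permutation_null_mean_matches_closed_form(self):
        rng = np.random.default_rng(4)
        n = 25
        W = lattice_adjacency(5, 5)
        rep = morans_i(rng.normal(size=n), W, n_permutations=2000, seed=1)
        assert rep["null_mean"] == pytest.approx(-1 / (n - 1), abs=0.02)
        assert 0 < rep["p_value"] <= 1

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(9), lattice_adjacency(3, 3))

    def test_queen_adjacency_from_polygons(self, small_survey):
        W = queen_adjacency(small_survey.region.districts)
        assert (W == W.T).all()
        assert W.sum() > 0 and np.diag(W).sum() == 0
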