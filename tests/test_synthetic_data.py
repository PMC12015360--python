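import io

import numpy as np
import pandas as pd
import pytest

from geoqual.geostat import CORRELATION_AT_RANGE
from geoqual.indicators import compute_indicator
from geoqual.synthetic_data import (SimulationConfig, make_region,
                                    simulate_clusters_and_counts,
                                    simulate_latent_field, simulate_nightlight,
                                    simulate_records, simulate_survey)


def tiny_config(**kw):
    base = dict(seed=7, n_clusters=30, grid_shape=(8, 8), n_districts=3,
                mean_cluster_size=15.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestRegion:
    def test_districts_partition_the_grid(self):
        region = make_region(tiny_config())
        dmap = region.district_map
        assert set(np.unique(dmap)) == set(range(3))

    def test_single_district_covers_everything(self):
        region = make_region(tiny_config(n_districts=1))
        assert (region.district_map == 0).all()

    def test_population_strictly_positive(self):
        region = make_region(tiny_config())
        assert (region.population.values > 0).all()

    def test_infeasible_partition_raises(self):
        with pytest.raises(ValueError):
            make_region(tiny_config(grid_shape=(2, 2), n_districts=5))

    def test_same_seed_identical_serialized_outputs(self, tmp_path):
        outs = []
        for _ in range(2):
            sv = simulate_survey(tiny_config())
            buf = io.StringIO()
            sv.clusters.to_csv(buf, index=False)
            a = tmp_path / "p.asc"
            sv.region.population.write_ascii(a)
            outs.append(buf.getvalue() + a.read_text())
        assert outs[0] == outs[1]


class TestLatentField:
    def test_zero_variance_gives_zero_field(self):
        region = make_region(tiny_config())
        f = simulate_latent_field(region, 0.0, 50.0, seed=1)
        assert (f.omega == 0).all()

    def test_marginal_variance_matches_within_monte_carlo_error(self):
        region = make_region(tiny_config(grid_shape=(6, 6)))
        sigma2 = 1.5
        reps = np.array([simulate_latent_field(region, sigma2, 40.0, seed=s).omega[10]
                         for s in range(200)])
        # var of a sample variance of n normals ~ 2 sigma^4 / n
        se = sigma2 * np.sqrt(2.0 / 200)
        assert abs(reps.var(ddof=1) - sigma2) < 3 * se

    def test_correlation_at_range_distance(self):
        # two cells exactly range_km apart: correlation sqrt(8) K1(sqrt 8)
        cfg = tiny_config(grid_shape=(1, 2), cell_km=60.0, n_districts=1)
        region = make_region(cfg)
        draws = np.array([simulate_latent_field(region, 1.0, 60.0, seed=s).omega
                          for s in range(400)])
        r = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        se = (1 - CORRELATION_AT_RANGE ** 2) / np.sqrt(400)
        assert abs(r - CORRELATION_AT_RANGE) < 3 * se


class TestClusters:
    def test_cluster_placement_proportional_to_population(self):
        cfg = tiny_config(grid_shape=(1, 2), n_districts=1, n_clusters=2000)
        region = make_region(cfg)
        region.population.values[:] = [[100.0, 300.0]]
        field = simulate_latent_field(region, 0.0, 50.0, seed=0)
        counts = simulate_clusters_and_counts(region, field, cfg)
        share = (counts["col"] == 1).mean()
        se = np.sqrt(0.75 * 0.25 / 2000)
        assert abs(share - 0.75) < 3 * se

    def test_null_parameters_give_half_proportion(self):
        cfg = tiny_config(beta=(0.0,), sigma2_spatial=0.0, sigma2_nugget=0.0,
                          n_clusters=200)
        sv = simulate_survey(cfg)
        pooled = sv.clusters["y"].sum() / sv.clusters["m"].sum()
        se = 0.5 / np.sqrt(sv.clusters["m"].sum())
        assert abs(pooled - 0.5) < 3 * se

    def test_binomial_support(self, small_survey):
        c = small_survey.clusters
        assert ((c["y"] >= 0) & (c["y"] <= c["m"])).all()
        assert (c["m"] >= 1).all()

    def test_zero_population_raises(self):
        cfg = tiny_config()
        region = make_region(cfg)
        region.population.values[:] = 0.0
        field = simulate_latent_field(region, 0.0, 50.0, seed=0)
        with pytest.raises(ValueError, match="population"):
            simulate_clusters_and_counts(region, field, cfg)


class TestRecords:
    @pytest.mark.parametrize("link", ["age_heaping", "incomplete_age", "flagged_haz"])
    def test_round_trip_exact_counts(self, link):
        cfg = tiny_config(heaping_link=link)
        sv = simulate_survey(cfg, exact_counts=True)
        counts = compute_indicator(sv.records, link)
        merged = counts.merge(sv.clusters, on="cluster_id",
                              suffixes=("_rec", "_true"))
        assert (merged["y_rec"] == merged["y_true"]).all()
        assert (merged["m_rec"] == merged["m_true"]).all()

    def test_stochastic_heaping_inversion_at_baseline(self):
        # W = 0.2 means no injected heaping: indicator ~ 20% over many records
        cfg = tiny_config(n_clusters=50, mean_cluster_size=40.0)
        sv = simulate_survey(cfg)
        clusters = sv.clusters.copy()
        clusters["p_true"] = 0.2
        recs = simulate_records(clusters, cfg, seed=9, exact_counts=False)
        counts = compute_indicator(recs, "age_heaping")
        share = counts["y"].sum() / counts["m"].sum()
        se = np.sqrt(0.2 * 0.8 / counts["m"].sum())
        assert abs(share - 0.2) < 3 * se

    def test_stochastic_heaping_saturation(self):
        cfg = tiny_config(n_clusters=5)
        sv = simulate_survey(cfg)
        clusters = sv.clusters.copy()
        clusters["p_true"] = 1.0
        recs = simulate_records(clusters, cfg, seed=9, exact_counts=False)
        assert (recs.roster["reported_age"] % 5 == 0).all()

    def test_subbaseline_heaping_target_rejected(self):
        cfg = tiny_config()
        sv = simulate_survey(cfg)
        clusters = sv.clusters.copy()
        clusters["p_true"] = 0.1
        with pytest.raises(ValueError, match="baseline"):
            simulate_records(clusters, cfg, seed=9, exact_counts=False)


class TestNightlight:
    def test_dn_contract_and_town_brightness(self, small_survey):
        dn = small_survey.nightlight
        v = dn.values
        assert v.min() >= 0 and v.max() <= 63
        assert (v == np.round(v)).all()
        assert v.max() >= 15  # at least one town centre is lit

    def test_zero_towns_all_dark(self):
        cfg = tiny_config(n_towns=0)
        region = make_region(cfg)
        dn = simulate_nightlight(region, cfg)
        assert (dn.values == 0).all()
        from geoqual.remoteness import distance_to_lit

        clusters = pd.DataFrame({"cluster_id": [0], "x_km": [5.0], "y_km": [5.0]})
        with pytest.raises(ValueError, match="15"):
            distance_to_lit(clusters, dn)
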