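"""Synthetic seascape generator: covariates, surveys, observations."""

import numpy as np
import pandas as pd
import pytest

from ffagg import SimulationConfig, simulate_covariates, simulate_surveys
from ffagg.simulate import simulate_observations, simulate_occurrence_grid


class TestConfig:
    def test_default_world_size(self):
        cfg = SimulationConfig()
        g = cfg.grid()
        assert g.n_cells == 2500
        assert g.n_blocks == 25

    def test_season_logits_reproduce_psi(self):
        from scipy.special import expit

        cfg = SimulationConfig()
        sp = cfg.season_params
        assert expit(sp["alpha1"]) == pytest.approx(0.7)
        assert expit(sp["alpha1"] + sp["beta_sea"]["winter"]) == pytest.approx(0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(coverage=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(r=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(beta=(1.0, 2.0))


class TestCovariates:
    def test_standardized_smooth_fields(self):
        cfg = SimulationConfig(seed=5)
        cov = simulate_covariates(cfg)
        vals = cov.drop(columns=["cell_id", "survey_id"])
        assert np.allclose(vals.mean(), 0, atol=1e-10)
        assert np.allclose(vals.std(ddof=0), 1, atol=1e-6)

    def test_spatial_smoothness_vs_rough_limit(self):
        g = SimulationConfig(seed=5).grid()
        smooth = simulate_covariates(SimulationConfig(seed=5))
        rough = simulate_covariates(SimulationConfig(seed=5, smoothness_km=0.01))

        def neighbor_corr(cov):
            f = cov["bpi"].to_numpy().reshape(g.ny, g.nx)
            return np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]

        assert neighbor_corr(smooth) > 0.8
        assert abs(neighbor_corr(rough)) < 0.1

    def test_requested_cross_correlation_achieved(self):
        cfg = SimulationConfig(seed=9, cross_corr=((0, 1, 0.9),))
        cov = simulate_covariates(cfg)
        r = np.corrcoef(cov["bpi"], cov["log_depth"])[0, 1]
        assert 0.8 <= r <= 0.97

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_covariates(SimulationConfig(cross_corr=((0, 1, 1.5),)))

    def test_seeded_determinism_and_dynamic_variation(self):
        cfg = SimulationConfig(seed=5)
        g = cfg.grid()
        surveys, _ = simulate_surveys(cfg, g)
        a = simulate_covariates(cfg, g, surveys)
        b = simulate_covariates(cfg, g, surveys)
        pd.testing.assert_frame_equal(a, b)
        # static covariates repeat across surveys, dynamic ones vary
        by_survey = a.groupby("survey_id")
        first, second = [gdf for _, gdf in list(by_survey)[:2]]
        assert np.allclose(first["bpi"].to_numpy(), second["bpi"].to_numpy())
        assert not np.allclose(first["sst_anom"].to_numpy(), second["sst_anom"].to_numpy())

    def test_collinear_column_for_screening(self):
        cfg = SimulationConfig(seed=5)
        cov = simulate_covariates(cfg, include_collinear=True)
        r = np.corrcoef(cov["bpi"], cov["collinear_with_bpi"])[0, 1]
        assert r > 0.9


class TestSurveys:
    def test_full_coverage_limit(self):
        cfg = SimulationConfig(
            extent=(0, 0, 40, 40), coarse_factor=5, coverage=1.0, strip_width_km=4.0, seed=2
        )
        _, effort = simulate_surveys(cfg)
        per_survey = effort.groupby("survey_id")
        assert all(len(gdf) == 100 for _, gdf in per_survey)
        assert np.allclose(effort["effort_km2"], 16.0)

    def test_coverage_near_target(self):
        cfg = SimulationConfig(seed=3)
        _, effort = simulate_surveys(cfg)
        area = 200.0 * 200.0
        cov = effort.groupby("survey_id")["effort_km2"].sum() / area
        assert np.all(np.abs(cov / cfg.coverage - 1) < 0.2)

    def test_effort_never_exceeds_cell_area(self):
        cfg = SimulationConfig(seed=3)
        _, effort = simulate_surveys(cfg)
        assert effort["effort_km2"].max() <= 16.0 + 1e-9
        assert effort["effort_km2"].min() > 0

    def test_two_surveys_per_season(self):
        surveys, _ = simulate_surveys(SimulationConfig(seed=3))
        assert surveys["season"].value_counts().eq(2).all()


class TestObservations:
    @pytest.fixture(scope="class")
    def world(self):
        cfg = SimulationConfig(extent=(0, 0, 80, 80), coarse_factor=10, coverage=0.3, seed=8)
        g = cfg.grid()
        surveys, effort = simulate_surveys(cfg, g)
        cov = simulate_covariates(cfg, g, surveys)
        return cfg, g, surveys, effort, cov

    def test_psi_zero_means_no_counts(self, world):
        cfg, g, surveys, effort, cov = world
        cfg0 = SimulationConfig(
            extent=cfg.extent, coarse_factor=cfg.coarse_factor, coverage=cfg.coverage,
            seed=cfg.seed, season_psi={s: 0.0 for s in ("summer", "autumn", "spring", "winter")},
        )
        counts, sizes, _ = simulate_observations(cfg0, cov, effort, surveys, g)
        assert counts["count"].sum() == 0
        assert sizes.empty

    def test_mean_matches_theta_under_certain_presence(self):
        # z == 1 everywhere and large r: y / effort averages to theta
        cfg = SimulationConfig(
            extent=(0, 0, 16, 16), coarse_factor=4, coverage=1.0, strip_width_km=4.0,
            surveys_per_season=60, seed=13, r=400.0,
            season_psi={s: 1.0 for s in ("summer", "autumn", "spring", "winter")},
            tau_car=1e6, beta=(0,) * 10, intercept=0.5, smoothness_km=0.01,
        )
        g = cfg.grid()
        surveys, effort = simulate_surveys(cfg, g)
        cov = simulate_covariates(cfg, g, surveys)
        counts, _, truth = simulate_observations(cfg, cov, effort, surveys, g)
        rate = counts["count"] / counts["effort_km2"]
        theta = np.exp(cfg.intercept)
        se = rate.std() / np.sqrt(len(rate))
        assert abs(rate.mean() - theta) < 3 * se

    def test_overdispersion_when_r_small(self, world):
        cfg, g, surveys, effort, cov = world
        cfg_od = SimulationConfig(
            extent=cfg.extent, coarse_factor=cfg.coarse_factor, coverage=cfg.coverage,
            seed=cfg.seed, r=0.3,
            season_psi={s: 1.0 for s in ("summer", "autumn", "spring", "winter")},
        )
        counts, _, _ = simulate_observations(cfg_od, cov, effort, surveys, g)
        y = counts["count"]
        assert y.var() > 2 * y.mean()  # far beyond Poisson

    def test_truth_record_complete_and_reproducible(self, world):
        cfg, g, surveys, effort, cov = world
        c1, s1, t1 = simulate_observations(cfg, cov, effort, surveys, g)
        c2, s2, t2 = simulate_observations(cfg, cov, effort, surveys, g)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(s1, s2)
        assert np.array_equal(t1["u1"], t2["u1"])
        assert set(t1) >= {"intercept", "beta", "r", "gamma", "tau_car", "u1",
                           "alpha1", "beta_sea", "beta_size", "sigma_size", "u2"}

    def test_sizes_lognormal_around_truth(self, world):
        cfg, g, surveys, effort, cov = world
        _, sizes, truth = simulate_observations(cfg, cov, effort, surveys, g)
        assert (sizes["area_m2"] > 0).all()
        resid = sizes["log_area"] - (
            truth["size_intercept"]
            + sizes[list(truth["beta_size"])].to_numpy() @ np.array(list(truth["beta_size"].values()))
            + np.asarray(truth["u2"])[sizes["block"]]
        )
        assert resid.std() == pytest.approx(cfg.sigma_size, rel=0.1)
        assert abs(resid.mean()) < 3 * cfg.sigma_size / np.sqrt(len(resid))


class TestOccurrenceGrid:
    def test_probabilities_clipped(self):
        cfg = SimulationConfig(extent=(0, 0, 80, 80), coarse_factor=10, seed=3)
        occ, labels = simulate_occurrence_grid(cfg, n_species=6, n_types=3, separation=8.0)
        P = occ.drop(columns="cell_id").to_numpy()
        assert P.min() >= 0.001 and P.max() <= 0.999
        assert len(labels) == len(occ)

    def test_zero_separation_unclusterable(self):
        from sklearn.metrics import adjusted_rand_score

        from ffagg import cluster_communities

        cfg = SimulationConfig(extent=(0, 0, 80, 80), coarse_factor=10, seed=6)
        occ, labels = simulate_occurrence_grid(cfg, n_species=8, n_types=3, separation=0.0)
        typer = cluster_communities(occ.drop(columns="cell_id"), [3], seed=1)
        assert abs(adjusted_rand_score(labels, typer.labels_)) < 0.05

    def test_n_types_validated(self):
        with pytest.raises(ValueError):
            simulate_occurrence_grid(SimulationConfig(), n_types=1)
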