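"""Covariate screening, standardization, richness, community typing."""

import numpy as np
import pandas as pd
import pytest

from ffagg import (
    CovariateStandardizer,
    SimulationConfig,
    cluster_communities,
    community_prevalence,
    ffa_density_by_type,
    screen_covariates,
    simulate_occurrence_grid,
    species_richness,
    standardize,
)


def covariate_table(rng, n=200):
    return pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))


class TestScreening:
    def test_correlated_pair_loses_one(self, rng):
        t = covariate_table(rng)
        t["e"] = t["a"] * 0.97 + 0.1 * rng.standard_normal(len(t))
        kept, report = screen_covariates(t)
        assert len(kept) == 4
        assert {"a", "e"} - set(kept)  # exactly one of the pair dropped
        assert len(report) == 1

    def test_orthogonal_columns_all_retained(self, rng):
        t = covariate_table(rng, n=500)
        kept, report = screen_covariates(t)
        assert kept == list("abcd")
        assert report.empty

    def test_linear_combination_dropped_first_by_vif(self, rng):
        t = covariate_table(rng)
        t["s"] = t["a"] + t["b"] + 1e-3 * rng.standard_normal(len(t))
        kept, report = screen_covariates(t)
        assert report.iloc[0]["covariate"] == "s"  # highest VIF goes first
        assert "VIF" in report.iloc[0]["reason"]

    def test_idempotence(self, rng):
        t = covariate_table(rng)
        t["e"] = t["a"] + 0.2 * rng.standard_normal(len(t))
        kept, _ = screen_covariates(t)
        kept2, report2 = screen_covariates(t[kept])
        assert kept2 == kept
        assert report2.empty

    def test_thresholds_enforced(self, rng):
        from ffagg.community import _vif

        t = covariate_table(rng, n=300)
        for j in range(3):
            t[f"x{j}"] = t["a"] * 0.8 + t.iloc[:, j] * 0.5 + 0.3 * rng.standard_normal(len(t))
        kept, _ = screen_covariates(t)
        corr = t[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.6
        assert _vif(t[kept].to_numpy()).max() < 3.0

    def test_constant_column_dropped_with_warning(self, rng):
        t = covariate_table(rng)
        t["k"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            kept, report = screen_covariates(t)
        assert "k" not in kept


class TestStandardize:
    def test_basic_column(self):
        out, tr = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["x"], [-1, 0, 1])  # sample SD (ddof=1) = 1

    def test_round_trip(self, rng):
        t = covariate_table(rng)
        out, tr = standardize(t)
        back = tr.inverse_transform(out)
        assert np.allclose(back.to_numpy(), t.to_numpy(), atol=1e-12)
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert np.allclose(out.std(ddof=1), 1, atol=1e-12)

    def test_stored_transform_applied_to_new_data(self, rng):
        train = pd.DataFrame({"x": rng.normal(5, 2, 100)})
        tr = CovariateStandardizer().fit(train)
        new = pd.DataFrame({"x": [5.0]})
        # uses TRAINING mean/sd, not the new data's
        assert tr.transform(new)["x"].iloc[0] == pytest.approx(
            (5.0 - train["x"].mean()) / train["x"].std(ddof=1)
        )

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestRichness:
    def test_bounds_and_arithmetic(self):
        occ = pd.DataFrame(np.full((5, 14), 0.5))
        assert np.allclose(species_richness(occ), 7.0)
        assert np.allclose(species_richness(pd.DataFrame(np.ones((3, 6)))), 6.0)
        assert np.allclose(species_richness(pd.DataFrame(np.zeros((3, 6)))), 0.0)

    def test_linearity_over_disjoint_species_sets(self, rng):
        a = pd.DataFrame(rng.uniform(0, 1, (20, 5)))
        b = pd.DataFrame(rng.uniform(0, 1, (20, 7)))
        joint = pd.concat([a, b], axis=1)
        assert np.allclose(
            species_richness(joint), species_richness(a) + species_richness(b)
        )

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            species_richness(pd.DataFrame([[1.2]]))


class TestCommunityTyping:
    def test_planted_clusters_recovered(self):
        cfg = SimulationConfig(extent=(0, 0, 80, 80), coarse_factor=10, seed=3)
        occ, labels = simulate_occurrence_grid(cfg, n_species=10, n_types=3, separation=4.0)
        typer = cluster_communities(occ.drop(columns="cell_id"), range(2, 7), seed=0)
        assert typer.k_ == 3
        # perfect recovery up to permutation
        tab = pd.crosstab(labels, typer.labels_)
        assert (tab.to_numpy() > 0).sum() == 3

    def test_type_one_is_richest(self):
        cfg = SimulationConfig(extent=(0, 0, 80, 80), coarse_factor=10, seed=4)
        occ, _ = simulate_occurrence_grid(cfg, n_species=8, n_types=3, separation=3.0)
        typer = cluster_communities(occ.drop(columns="cell_id"), range(2, 6), seed=0)
        rich = species_richness(occ.drop(columns="cell_id"))
        means = [rich[typer.labels_ == t].mean() for t in range(1, typer.k_ + 1)]
        assert means == sorted(means, reverse=True)

    def test_identical_rows_degenerate(self):
        occ = pd.DataFrame(np.full((30, 4), 0.4))
        with pytest.warns(UserWarning):
            typer = cluster_communities(occ, range(2, 5), seed=0)
        assert typer.k_ == 2

    def test_duplicated_rows_leave_centroids_unchanged(self, rng):
        # well-separated planted clusters: the optimum is unambiguous, so
        # doubling every row must reproduce the same centroids
        centers = np.array([[0.1] * 5, [0.5] * 5, [0.9] * 5])
        occ = pd.DataFrame(
            np.clip(centers.repeat(15, axis=0) + 0.01 * rng.standard_normal((45, 5)), 0, 1)
        )
        t1 = cluster_communities(occ, [3], seed=0)
        t2 = cluster_communities(pd.concat([occ, occ], ignore_index=True), [3], seed=0)
        c1 = np.sort(t1.centroids_.to_numpy(), axis=0)
        c2 = np.sort(t2.centroids_.to_numpy(), axis=0)
        assert np.allclose(c1, c2, atol=1e-9)

    def test_k_exceeding_distinct_rows_rejected(self):
        occ = pd.DataFrame(np.tile(np.linspace(0.1, 0.4, 4)[:, None], (3, 3)))
        with pytest.raises(ValueError):
            cluster_communities(occ, [8], seed=0)


class TestPrevalence:
    def test_single_type_is_column_means(self, rng):
        occ = pd.DataFrame(rng.uniform(0, 1, (25, 4)), columns=list("wxyz"))
        prev, rich = community_prevalence(occ, np.ones(25, dtype=int))
        assert np.allclose(prev.loc[1], occ.mean())
        assert rich.loc[0, "richness_mean"] == pytest.approx(
            species_richness(occ).mean()
        )

    def test_planted_two_type_recovery(self, rng):
        n = 400
        labels = np.repeat([1, 2], n // 2)
        pA = np.where(labels == 1, 0.9, 0.1)
        occ = pd.DataFrame(
            {"A": np.clip(pA + 0.02 * rng.standard_normal(n), 0, 1),
             "B": rng.uniform(0, 1, n)}
        )
        prev, _ = community_prevalence(occ, labels)
        assert prev.loc[1, "A"] == pytest.approx(0.9, abs=0.05)
        assert prev.loc[2, "A"] == pytest.approx(0.1, abs=0.05)
        assert ((prev >= 0) & (prev <= 1)).all().all()


class TestFFADensity:
    def test_two_cell_arithmetic(self):
        out = ffa_density_by_type(np.array([4.0, 0.0]), np.array([1, 1]))
        row = out.iloc[0]
        assert row.ffa_mean == pytest.approx(2.0)
        assert row.ffa_sd == pytest.approx(np.sqrt(8))  # sample SD of (4, 0)
        assert row.density_per_km2 == pytest.approx(4 / 32)

    def test_zero_density_type(self):
        out = ffa_density_by_type(np.zeros(6), np.full(6, 2))
        assert out.iloc[0].density_per_km2 == 0.0

    def test_order_invariance_and_missing_types(self, rng):
        v = rng.poisson(3, 30).astype(float)
        lab = rng.choice([1, 3], 30)
        perm = rng.permutation(30)
        a = ffa_density_by_type(v, lab, all_types=[1, 2, 3])
        b = ffa_density_by_type(v[perm], lab[perm], all_types=[1, 2, 3])
        pd.testing.assert_frame_equal(a, b)
        assert np.isnan(a.set_index("community_type").loc[2, "density_per_km2"])
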