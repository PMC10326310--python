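import numpy as np
import pandas as pd
import pytest

from sdmpanel.synthetic import (
    DGPConfig,
    generate_covariates,
    generate_map,
    generate_outcome,
    generate_panel,
)
from sdmpanel.weights import contiguity_from_adjacency, row_standardize


class TestConfig:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            DGPConfig(sigma=-1.0)

    def test_zero_sd_moment_target_rejected(self):
        with pytest.raises(ValueError, match="moment"):
            DGPConfig(covariate_moments={"x": (1.0, 0.0)},
                      beta=(0.1,), theta=(0.0,))

    def test_coefficient_length_must_match_covariates(self):
        with pytest.raises(ValueError, match="length"):
            DGPConfig(beta=(0.1, 0.2), theta=(0.0, 0.0),
                      covariate_moments={"x": (0.0, 1.0)})


class TestMap:
    def test_connected_graph_and_four_regions(self):
        coords, adjacency, part = generate_map(30, seed=0)
        import networkx as nx
        g = nx.Graph(adjacency)
        g.add_nodes_from(coords.index)
        assert nx.is_connected(g)
        counts = pd.Series(part).value_counts()
        assert len(counts) == 4 and (counts > 0).all()

    def test_deterministic_under_seed(self):
        a = generate_map(20, seed=3)
        b = generate_map(20, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[1] == b[1] and a[2] == b[2]

    def test_partition_needs_eight_units(self):
        with pytest.raises(ValueError, match="at least 8"):
            generate_map(4, seed=0)
        coords, adjacency, part = generate_map(4, seed=0, partition=False)
        assert part is None

    def test_regions_spatially_coherent(self):
        """Each region occupies one quadrant-like block of the plane."""
        coords, _, part = generate_map(40, seed=1)
        med_x = coords["x"].median()
        west = {u for u, r in part.items() if r in ("western", "northeast")}
        east = {u for u, r in part.items() if r in ("central", "eastern")}
        assert all(coords.loc[u, "x"] <= med_x for u in west) or \
            all(coords.loc[u, "x"] >= med_x for u in east)


class TestCovariates:
    def test_moment_targets_hit_within_sampling_error(self):
        """Sample means sit within 3 SEs of their targets, where the SE of
        the mean accounts for the unit-heterogeneity and AR(1) dependence
        built into the design (closed form derived independently)."""
        config = DGPConfig()
        n, T = config.n, config.T
        phi, w = config.persistence, config.unit_share
        # time-mean variance of a unit-variance AR(1): (1/T^2) sum phi^|s-t|
        g = (T + 2 * sum((T - d) * phi**d for d in range(1, T))) / T**2
        var_mean = w / n + (1 - w) * g / n
        for seed in (10, 11, 12):
            cov = generate_covariates(config, seed=seed)
            for var, (mean, sd) in config.covariate_moments.items():
                tol = 3 * sd * np.sqrt(var_mean)
                assert cov[var].mean() == pytest.approx(mean, abs=tol), \
                    (var, seed)

    def test_pooled_sd_near_target(self):
        config = DGPConfig()
        cov = generate_covariates(config, seed=10)
        for var, (_, sd) in config.covariate_moments.items():
            assert cov[var].std() == pytest.approx(sd, rel=0.25), var

    def test_zero_persistence_kills_serial_correlation(self):
        config = DGPConfig(persistence=0.0, unit_share=0.0)
        rs = []
        for seed in range(10):
            cov = generate_covariates(config, seed=seed)
            x = cov["lnRTI"].unstack().to_numpy()
            rs.append(np.corrcoef(x[:, :-1].ravel(), x[:, 1:].ravel())[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_determinism(self):
        config = DGPConfig()
        pd.testing.assert_frame_equal(generate_covariates(config, seed=4),
                                      generate_covariates(config, seed=4))


class TestOutcome:
    @pytest.fixture(scope="class")
    def small_world(self):
        coords, adjacency, part = generate_map(12, seed=6)
        W = row_standardize(
            contiguity_from_adjacency(adjacency, tuple(coords.index)))
        return W, part

    def test_noiseless_nonspatial_outcome_is_linear(self, small_world):
        W, _ = small_world
        config = DGPConfig(n=12, T=5, rho=0.0, theta=(0.0,) * 7,
                           sigma=0.0, fe_sd=0.0)
        cov = generate_covariates(config, seed=1)
        panel = generate_outcome(cov, W, config, seed=2)
        X = cov[list(config.covariates)].to_numpy()
        means = np.array([m for m, _ in config.covariate_moments.values()])
        alpha = config.outcome_mean - means @ np.array(config.beta)
        expect = X @ np.array(config.beta) + alpha
        got = panel.df["FME"].to_numpy()
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_reduced_form_residual_recovers_disturbance(self, small_world):
        W, _ = small_world
        config = DGPConfig(n=12, T=5, rho=-0.4)
        cov = generate_covariates(config, seed=3)
        panel, comp = generate_outcome(cov, W, config, seed=4,
                                       return_components=True)
        Y = panel.matrix("FME")
        A = np.eye(12) - config.rho * W.W
        np.testing.assert_allclose(A @ Y, comp["rhs"], atol=1e-10)

    def test_inadmissible_rho_rejected(self, small_world):
        W, _ = small_world
        config = DGPConfig(n=12, T=5, rho=1.2)
        cov = generate_covariates(config, seed=3)
        with pytest.raises(ValueError, match="admissible"):
            generate_outcome(cov, W, config, seed=4)

    def test_region_betas_require_partition(self, small_world):
        W, _ = small_world
        config = DGPConfig(n=12, T=5,
                           region_betas={"eastern": (0.0,) * 7})
        cov = generate_covariates(config, seed=3)
        with pytest.raises(ValueError, match="partition"):
            generate_outcome(cov, W, config, seed=4)


class TestBundle:
    def test_bit_identical_under_fixed_seed(self):
        a = generate_panel(DGPConfig(n=16, T=6), seed=8)
        b = generate_panel(DGPConfig(n=16, T=6), seed=8)
        pd.testing.assert_frame_equal(a["panel"].df, b["panel"].df)
        assert np.array_equal(a["W_contiguity"].W, b["W_contiguity"].W)
        assert a["partition"] == b["partition"]

    def test_outcome_mean_near_target(self):
        bundle = generate_panel(seed=21)
        assert bundle["panel"].df["FME"].mean() == pytest.approx(0.067,
                                                                 abs=0.03)

    def test_fitting_recovers_truth_loosely(self, map30):
        """Single-panel sanity: the SDM fit lands near the generating
        parameters (tight recovery bounds are exercised in the replicated
        acceptance checks)."""
        from sdmpanel.panel_model import SDMSpec, fit_sdm_fe
        from conftest import simulate_panel
        config = DGPConfig(rho=-0.5)
        panel = simulate_panel(map30["W"], config, seed=999)
        fit = fit_sdm_fe(panel, SDMSpec("FME", config.covariates, map30["W"]))
        assert fit.rho == pytest.approx(-0.5, abs=0.3)
        assert fit.beta[0] == pytest.approx(config.beta[0], abs=0.02)
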