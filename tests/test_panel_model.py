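import dataclasses

import numpy as np
import pytest

from sdmpanel.panel import PanelDataset
from sdmpanel.panel_model import (
    CollinearityError,
    SDMSpec,
    fit_sdm_fe,
    fit_sdm_re,
    fit_sem,
    fit_slm,
    fit_spatial_panel,
    hausman_test,
    lr_test,
    wald_reduction_tests,
)
from sdmpanel.synthetic import DGPConfig
from sdmpanel.weights import rho_interval

from conftest import simulate_panel


def within_ols_oracle(panel, outcome, covariates):
    """Normal-equations within-OLS estimator, independent of the ML path."""
    Y = panel.matrix(outcome)
    X = np.stack([panel.matrix(v) for v in covariates], axis=2)
    Yd = (Y - Y.mean(axis=1, keepdims=True)).reshape(-1)
    Xd = (X - X.mean(axis=1, keepdims=True)).reshape(-1, X.shape[2])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ Yd)


class TestSpec:
    def test_duplicate_covariates_rejected(self, map30):
        with pytest.raises(ValueError, match="duplicate"):
            SDMSpec("FME", ("a", "a"), map30["W"])

    def test_outcome_among_covariates_rejected(self, map30):
        with pytest.raises(ValueError, match="outcome"):
            SDMSpec("FME", ("FME", "x"), map30["W"])


class TestLikelihoodMachinery:
    def test_logdet_eigen_matches_dense(self, map30):
        W = map30["W"].W
        eigs = map30["W"].eigs
        for rho in np.linspace(-0.9, 0.9, 19):
            dense = np.linalg.slogdet(np.eye(30) - rho * W)[1]
            assert np.sum(np.log(1 - rho * eigs)) == pytest.approx(
                dense, abs=1e-10)

    def test_fixed_rho_zero_slm_equals_within_ols(self, map30, default_config):
        panel = simulate_panel(map30["W"], default_config, seed=31)
        spec = SDMSpec("FME", default_config.covariates, map30["W"],
                       "fixed", "SLM")
        fit = fit_spatial_panel(panel, spec, fix_rho=0.0)
        oracle = within_ols_oracle(panel, "FME", default_config.covariates)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-8)

    def test_profiled_loglik_beats_restricted(self, fitted_sdm):
        fit, panel, spec = fitted_sdm
        at_zero = fit_spatial_panel(panel, spec, fix_rho=0.0)
        assert fit.loglik >= at_zero.loglik

    def test_rho_inside_admissible_interval(self, fitted_sdm):
        fit, _, _ = fitted_sdm
        lo, hi = fit.rho_bounds
        assert lo < fit.rho < hi

    def test_sigma2_positive_and_vcov_psd(self, fitted_sdm):
        fit, _, _ = fitted_sdm
        assert fit.sigma2 > 0
        V = fit.vcov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > -1e-10

    def test_collinear_design_rejected(self, map30, default_config):
        panel = simulate_panel(map30["W"], default_config, seed=31)
        panel = panel.with_variable("double", 2 * panel.df["lnRTI"])
        spec = SDMSpec("FME", default_config.covariates + ("double",),
                       map30["W"])
        with pytest.raises(CollinearityError):
            fit_sdm_fe(panel, spec)


class TestRecovery:
    def test_null_spatial_dgp_gives_small_rho(self, map30):
        config = DGPConfig(rho=0.0, theta=(0.0,) * 7)
        rhos, betas = [], []
        for seed in range(20):
            panel = simulate_panel(map30["W"], config, seed=400 + seed)
            fit = fit_sdm_fe(
                panel, SDMSpec("FME", config.covariates, map30["W"]))
            rhos.append(fit.rho)
            betas.append(fit.beta)
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < max(2 * se, 0.03)
        np.testing.assert_allclose(np.mean(betas, axis=0), config.beta,
                                   atol=0.02)

    def test_estimates_invariant_to_unit_relabeling(self, map30,
                                                    default_config):
        panel = simulate_panel(map30["W"], default_config, seed=55)
        spec = SDMSpec("FME", default_config.covariates, map30["W"])
        fit = fit_sdm_fe(panel, spec)
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(list(panel.unit_ids)))
        panel_p = panel.subset_units(perm)
        spec_p = SDMSpec("FME", default_config.covariates,
                         map30["W"].subset(perm))
        fit_p = fit_sdm_fe(panel_p, spec_p)
        assert fit_p.rho == pytest.approx(fit.rho, abs=1e-7)
        np.testing.assert_allclose(fit_p.beta, fit.beta, atol=1e-7)

    def test_rmse_shrinks_with_longer_panels(self, map30):
        """More periods at a fixed DGP reduce the rho estimation error."""
        rmse = []
        for T in (6, 24):
            config = DGPConfig(rho=-0.5, T=T)
            errs = [
                fit_sdm_fe(
                    simulate_panel(map30["W"], config, seed=900 + T + s),
                    SDMSpec("FME", config.covariates, map30["W"])).rho + 0.5
                for s in range(15)
            ]
            rmse.append(np.sqrt(np.mean(np.square(errs))))
        assert rmse[1] < rmse[0]


class TestRandomEffects:
    def test_zero_unit_effect_variance_detected(self, map30):
        config = DGPConfig(rho=-0.5, fe_sd=0.0)
        panel = simulate_panel(map30["W"], config, seed=13)
        with pytest.warns(UserWarning, match="zero boundary"):
            re = fit_sdm_re(panel, SDMSpec("FME", config.covariates,
                                           map30["W"]))
        assert re.re_variance == pytest.approx(0.0, abs=1e-5)
        # estimates centred on the truth within 3 standard errors each
        se = re.bse[list(config.covariates)].to_numpy()
        assert np.all(np.abs(re.beta - config.beta) < 3 * se)

    def test_correlated_effects_bias_re_not_fe(self, map30):
        """With unit effects correlated with x1, FE stays centered on the
        truth while RE drifts (the classic Hausman setting)."""
        config = DGPConfig(rho=-0.5, fe_sd=0.15, fe_x_corr=0.9)
        fe_err, re_err = [], []
        for seed in range(25):
            panel = simulate_panel(map30["W"], config, seed=700 + seed)
            spec = SDMSpec("FME", config.covariates, map30["W"])
            fe_err.append(fit_sdm_fe(panel, spec).beta[0] - config.beta[0])
            re_err.append(fit_sdm_re(panel, spec).beta[0] - config.beta[0])
        assert abs(np.mean(re_err)) > 2 * abs(np.mean(fe_err))

    def test_fe_and_re_both_return_valid_fits(self, map30, default_config):
        panel = simulate_panel(map30["W"], default_config, seed=14)
        spec = SDMSpec("FME", default_config.covariates, map30["W"])
        for fit in (fit_sdm_fe(panel, spec), fit_sdm_re(panel, spec)):
            assert np.isfinite(fit.loglik)
            assert np.isfinite(fit.vcov.to_numpy()).all()


class TestNestedModels:
    def test_sdm_loglik_dominates_slm(self, map30, default_config):
        panel = simulate_panel(map30["W"], default_config, seed=17)
        spec = SDMSpec("FME", default_config.covariates, map30["W"])
        sdm = fit_sdm_fe(panel, spec)
        slm = fit_slm(panel, spec)
        assert sdm.loglik >= slm.loglik - 1e-8

    def test_slm_close_to_sdm_under_theta_zero_dgp(self, map30):
        config = DGPConfig(rho=-0.5, theta=(0.0,) * 7)
        panel = simulate_panel(map30["W"], config, seed=18)
        spec = SDMSpec("FME", config.covariates, map30["W"])
        lr = lr_test(fit_sdm_fe(panel, spec), fit_slm(panel, spec))
        assert lr.statistic < 30  # not a wild rejection of the truth

    def test_sem_on_independent_errors_gives_small_lambda(self, map30):
        config = DGPConfig(rho=0.0, theta=(0.0,) * 7)
        lams = []
        for seed in range(10):
            panel = simulate_panel(map30["W"], config, seed=500 + seed)
            lams.append(
                fit_sem(panel,
                        SDMSpec("FME", config.covariates, map30["W"])).rho)
        assert abs(np.mean(lams)) < 0.1


class TestSpecificationTests:
    def test_lr_identical_models_is_zero(self, fitted_sdm):
        fit, _, _ = fitted_sdm
        res = lr_test(fit, fit)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_lr_non_nested_rejected(self, map30, default_config):
        panel = simulate_panel(map30["W"], default_config, seed=19)
        spec = SDMSpec("FME", default_config.covariates, map30["W"])
        slm = fit_slm(panel, spec)
        sem = fit_sem(panel, spec)
        with pytest.raises(ValueError, match="nested"):
            lr_test(slm, sem)

    def test_lr_degrees_of_freedom(self, map30, default_config):
        panel = simulate_panel(map30["W"], default_config, seed=19)
        spec = SDMSpec("FME", default_config.covariates, map30["W"])
        sdm = fit_sdm_fe(panel, spec)
        assert lr_test(sdm, fit_slm(panel, spec)).df == 7
        assert lr_test(sdm, fit_sem(panel, spec)).df == 7

    def test_wald_zero_theta_gives_zero_statistic(self, fitted_sdm):
        fit, _, _ = fitted_sdm
        degenerate = dataclasses.replace(fit, theta=np.zeros(fit.k))
        h01, _ = wald_reduction_tests(degenerate)
        assert h01.statistic == 0.0

    def test_wald_invariant_to_covariate_reordering(self, map30,
                                                    default_config):
        panel = simulate_panel(map30["W"], default_config, seed=23)
        order1 = default_config.covariates
        order2 = tuple(reversed(order1))
        f1 = fit_sdm_fe(panel, SDMSpec("FME", order1, map30["W"]))
        f2 = fit_sdm_fe(panel, SDMSpec("FME", order2, map30["W"]))
        for a, b in zip(wald_reduction_tests(f1), wald_reduction_tests(f2)):
            assert a.statistic == pytest.approx(b.statistic, rel=1e-4)

    def test_wald_requires_sdm(self, map30, default_config):
        panel = simulate_panel(map30["W"], default_config, seed=23)
        slm = fit_slm(panel, SDMSpec("FME", default_config.covariates,
                                     map30["W"]))
        with pytest.raises(ValueError, match="SDM"):
            wald_reduction_tests(slm)

    def test_hausman_identical_coefficients_zero(self, fitted_sdm):
        fit, _, _ = fitted_sdm
        pseudo_re = dataclasses.replace(
            fit, spec=dataclasses.replace(fit.spec, effects="random"))
        res = hausman_test(fit, pseudo_re)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_hausman_contract(self, map30):
        """The FE-vs-RE contrast returns a nonnegative chi-square statistic
        with a valid p-value even when V_FE - V_RE is indefinite (the
        pseudo-inverse of its positive part is used)."""
        for seed in range(4):
            config = DGPConfig(rho=-0.5, fe_sd=0.15)
            panel = simulate_panel(map30["W"], config, seed=810 + seed)
            spec = SDMSpec("FME", config.covariates, map30["W"])
            res = hausman_test(fit_sdm_fe(panel, spec),
                               fit_sdm_re(panel, spec))
            assert res.statistic >= 0
            assert 0 <= res.p <= 1
            assert 1 <= res.df <= 14

    def test_hausman_argument_order_enforced(self, fitted_sdm):
        fit, _, _ = fitted_sdm
        with pytest.raises(ValueError, match="fixed fit, random fit"):
            hausman_test(fit, fit)
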