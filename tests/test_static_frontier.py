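import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

from selfthin.static_frontier import (
    composed_error_logpdf,
    fit_lme_reineke,
    fit_lqmm,
    fit_sfmm,
    select_quantile,
)

from conftest import frontier_plots


class TestLME:
    def test_noise_free_exact_fit(self):
        rng = np.random.default_rng(0)
        plots = frontier_plots(rng, 30, 3, beta=(12.0, -1.6), re_sd=0.0,
                               noise="gauss", sigma=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme_reineke(plots)
        assert fit.beta0 == pytest.approx(12.0, abs=1e-8)
        assert fit.beta1 == pytest.approx(-1.6, abs=1e-8)

    def test_singleton_plots_fall_back_with_warning(self):
        rng = np.random.default_rng(1)
        plots = frontier_plots(rng, 60, 1, re_sd=0.1, noise="gauss", sigma=0.1)
        with pytest.warns(UserWarning, match="one observation per plot"):
            fit = fit_lme_reineke(plots)
        assert not fit.random_slope
        assert np.isfinite(fit.se_beta0)

    def test_too_few_dg_values_error(self):
        df = pd.DataFrame(dict(plot_id=["a", "b"], n_ha=[1000.0, 900.0], dg_cm=[20.0, 20.0]))
        with pytest.raises(ValueError, match="distinct dg"):
            fit_lme_reineke(df)

    def test_plot_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        plots = frontier_plots(rng, 40, 3, re_sd=0.1, noise="gauss", sigma=0.1)
        relabeled = plots.copy()
        mapping = {p: f"z{i:03d}" for i, p in enumerate(reversed(plots["plot_id"].unique()))}
        relabeled["plot_id"] = relabeled["plot_id"].map(mapping)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_lme_reineke(plots)
            b = fit_lme_reineke(relabeled)
        # invariance holds up to the mixed-model optimizer's own tolerance
        assert a.beta0 == pytest.approx(b.beta0, abs=5e-3)
        assert a.beta1 == pytest.approx(b.beta1, abs=2e-3)


class TestLQMM:
    def test_median_fit_matches_pinball_oracle(self):
        """With the random-intercept variance pinned at zero, tau=0.5 ML under
        the ALD kernel is exactly median (pinball-loss) regression."""
        rng = np.random.default_rng(3)
        plots = frontier_plots(rng, 120, 1, re_sd=0.0, noise="gauss", sigma=0.3)
        fit = fit_lqmm(plots, tau=0.5, fit_random=False, seed=0)
        y = np.log(plots["n_ha"])
        X = sm.add_constant(np.log(plots["dg_cm"]))
        oracle = QuantReg(y, X).fit(q=0.5)
        assert fit.beta0_tau == pytest.approx(oracle.params.iloc[0], abs=1e-4)
        assert fit.beta1_tau == pytest.approx(oracle.params.iloc[1], abs=1e-4)

    def test_duplicated_rows_leave_estimates_unchanged(self):
        rng = np.random.default_rng(4)
        plots = frontier_plots(rng, 50, 1, re_sd=0.0, noise="ald", tau=0.9, sigma=0.1)
        doubled = pd.concat([plots, plots], ignore_index=True)
        a = fit_lqmm(plots, tau=0.9, fit_random=False, seed=0)
        b = fit_lqmm(doubled, tau=0.9, fit_random=False, seed=0)
        assert a.beta0_tau == pytest.approx(b.beta0_tau, abs=1e-4)
        assert a.beta1_tau == pytest.approx(b.beta1_tau, abs=1e-4)

    def test_tau_validation(self):
        df = frontier_plots(np.random.default_rng(0), 20, 1, noise="gauss")
        with pytest.raises(ValueError, match="tau"):
            fit_lqmm(df, tau=1.2)

    def test_mixed_fit_recovers_frontier_on_network(self, network):
        fit = fit_lqmm(network.plots, tau=0.95, seed=0)
        assert fit.beta0_tau == pytest.approx(12.15, abs=0.25)
        assert fit.beta1_tau == pytest.approx(-1.55, abs=0.12)
        assert fit.var_u0 >= 0.0 and fit.sigma_ala > 0.0


class TestSelectQuantile:
    def test_single_candidate(self):
        rng = np.random.default_rng(5)
        plots = frontier_plots(rng, 40, 1, re_sd=0.0, noise="ald", tau=0.9, sigma=0.1)
        tau, table = select_quantile(plots, [0.9], fit_random=False)
        assert tau == 0.9 and len(table) == 1

    def test_closure_over_candidates(self, static_plots):
        taus = [0.90, 0.95]
        tau, table = select_quantile(static_plots, taus, seed=0)
        assert tau in taus
        assert set(table["tau"]) <= set(taus)
        assert (table["var_sum"] > 0).all()

    def test_empty_candidates_error(self, static_plots):
        with pytest.raises(ValueError, match="empty"):
            select_quantile(static_plots, [])


class TestSFMM:
    def test_pure_gaussian_reduces_to_ols(self):
        rng = np.random.default_rng(17)
        plots = frontier_plots(rng, 600, 1, re_sd=0.0, noise="gauss", sigma=0.12)
        with pytest.warns(UserWarning, match="no inefficiency"):
            fit = fit_sfmm(plots, include_random=False, seed=0)
        y = np.log(plots["n_ha"])
        X = sm.add_constant(np.log(plots["dg_cm"]))
        ols = sm.OLS(y, X).fit()
        assert fit.sigma_u < 0.01
        assert fit.beta0 == pytest.approx(ols.params.iloc[0], abs=0.02)
        assert fit.beta1 == pytest.approx(ols.params.iloc[1], abs=0.01)

    def test_loglik_dominates_ols_nested_solution(self):
        rng = np.random.default_rng(7)
        plots = frontier_plots(rng, 150, 1, re_sd=0.0, noise="frontier")
        fit = fit_sfmm(plots, include_random=False, seed=0)
        y = np.log(plots["n_ha"]).to_numpy()
        X = sm.add_constant(np.log(plots["dg_cm"])).to_numpy()
        ols = sm.OLS(y, X).fit()
        resid = y - X @ ols.params
        ll_ols = float(np.sum(composed_error_logpdf(resid, np.std(resid), 1e-8)))
        assert fit.loglik >= ll_ols - 1e-6

    def test_composed_error_density_normalized(self):
        grid = np.linspace(-8, 8, 160001)
        dens = np.exp(composed_error_logpdf(grid, 0.6, 0.9))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_sml_and_quadrature_agree(self):
        rng = np.random.default_rng(8)
        plots = frontier_plots(rng, 80, 2, re_sd=0.1, noise="frontier")
        a = fit_sfmm(plots, method="quadrature", seed=0)
        b = fit_sfmm(plots, method="sml", n_sim=400, seed=0)
        assert a.beta0 == pytest.approx(b.beta0, abs=0.05)
        assert a.beta1 == pytest.approx(b.beta1, abs=0.02)

    def test_plot_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        plots = frontier_plots(rng, 60, 2, re_sd=0.1, noise="frontier")
        relabeled = plots.copy()
        mapping = {p: f"z{i:03d}" for i, p in enumerate(reversed(plots["plot_id"].unique()))}
        relabeled["plot_id"] = relabeled["plot_id"].map(mapping)
        a = fit_sfmm(plots, seed=0)
        b = fit_sfmm(relabeled, seed=0)
        assert a.beta0 == pytest.approx(b.beta0, abs=1e-4)
        assert a.beta1 == pytest.approx(b.beta1, abs=1e-4)
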