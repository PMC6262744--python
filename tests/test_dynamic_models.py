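import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from selfthin.dynamic_models import (
    build_transitions,
    density_closed_form,
    deaths_from_transitions,
    fit_density_model,
    fit_mortality_nbme,
    fit_trajectory_nlme,
    nb_mean,
    trajectory_mean,
)
from selfthin.synthetic_data import attractor_line, simulate_nb_transitions, simulate_trajectory

ODE_TRUTH = (np.log(1.55) - 12.15, 0.55, 2.0)


def plot_rows(pid, ns, dgs):
    return [dict(plot_id=pid, occasion=j, n_ha=n, dg_cm=d)
            for j, (n, d) in enumerate(zip(ns, dgs))]


def closed_form_transitions(rng, n_plots=15, noise=0.0, re_sd=0.0,
                            offsets=(-0.3, 0.45), n_trans=2):
    rows = []
    for i in range(n_plots):
        u = rng.normal(0, re_sd) if re_sd else 0.0
        b = (ODE_TRUTH[0] + u, ODE_TRUTH[1], ODE_TRUTH[2])
        ai, sl = attractor_line(b)
        dg0 = rng.uniform(10, 26)
        n0 = np.exp(ai + sl * np.log(dg0) + rng.uniform(*offsets))
        grid = dg0 + np.cumsum(np.r_[0.0, rng.uniform(2, 5, n_trans)])
        nn = simulate_trajectory(b, n0, grid)
        for j in range(n_trans):
            n1 = nn[j + 1] * np.exp(rng.normal(0, noise)) if noise else nn[j + 1]
            rows.append(dict(plot_id=f"p{i:03d}", N0=nn[j], N1=n1,
                             dg0=grid[j], dg1=grid[j + 1]))
    return pd.DataFrame(rows)


class TestTransitions:
    def test_consecutive_pairing(self):
        plots = pd.DataFrame(plot_rows("A", [3000, 2500, 2100], [14, 17, 20]))
        tr = build_transitions(plots)
        assert len(tr) == 2
        assert tr["N0"].tolist() == [3000, 2500]
        assert (tr["delta_n"] >= 0).all() and (tr["delta_dg"] > 0).all()

    def test_ingrowth_excluded(self):
        plots = pd.DataFrame(plot_rows("A", [3000, 3200, 2100], [14, 17, 20]))
        tr = build_transitions(plots)
        assert len(tr) == 1 and tr["N0"].iloc[0] == 3200

    def test_nonincreasing_dg_excluded(self):
        plots = pd.DataFrame(plot_rows("A", [3000, 2500], [17, 17]))
        with pytest.warns(UserWarning, match="no usable"):
            tr = build_transitions(plots)
        assert tr.empty

    def test_single_occasion_plots_skipped(self):
        plots = pd.DataFrame(plot_rows("A", [3000], [14]))
        with pytest.warns(UserWarning):
            assert build_transitions(plots).empty


class TestDensityModel:
    def test_noise_free_exact_recovery(self):
        tr = closed_form_transitions(np.random.default_rng(0), n_plots=15)
        fit = fit_density_model(tr, random_effect_specs=((),), seed=0)
        assert fit.beta0 == pytest.approx(ODE_TRUTH[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(ODE_TRUTH[1], abs=1e-6)
        assert fit.beta2 == pytest.approx(ODE_TRUTH[2], abs=1e-6)

    def test_single_spec_comparison_table(self):
        tr = closed_form_transitions(np.random.default_rng(1), n_plots=10)
        fit = fit_density_model(tr, random_effect_specs=(("beta0",),), seed=0)
        assert len(fit.comparison) == 1
        assert fit.random_effect_spec == ("beta0",)

    def test_best_bic_spec_selected_from_candidates(self):
        tr = closed_form_transitions(np.random.default_rng(2), n_plots=25,
                                     noise=0.01, re_sd=0.02, n_trans=3)
        fit = fit_density_model(
            tr, random_effect_specs=(("beta0",), ("beta2",)), seed=0)
        assert len(fit.comparison) == 2
        best_row = fit.comparison.loc[fit.comparison["bic"].idxmin()]
        assert best_row["spec"] == "+".join(fit.random_effect_spec)

    def test_closed_form_penalizes_extinct_bracket(self):
        mu = density_closed_form(2.0, 0.0, 0.5, np.array([10.0]),
                                 np.array([10.0]), np.array([400.0]))
        assert not np.isfinite(mu[0])

    def test_objective_minimal_at_truth_on_clean_data(self):
        tr = closed_form_transitions(np.random.default_rng(3), n_plots=12)
        mu = density_closed_form(*ODE_TRUTH, tr["N0"].values, tr["dg0"].values, tr["dg1"].values)
        assert np.abs(np.log(tr["N1"].values) - mu).max() < 1e-12


class TestMortality:
    def test_link_hand_value(self):
        mu = nb_mean((-10.0, 1.0, 1.0), 20.0, 1000.0, 2.0)
        assert mu == pytest.approx(1.8160, abs=2e-4)
        theta = 2.0
        assert mu + mu**2 / theta == pytest.approx(3.465, abs=2e-3)

    def test_recovery_fixed_effects(self):
        d = simulate_nb_transitions((-11.7, 0.55, 2.0), theta=5.0, n=500, seed=2)
        fit = fit_mortality_nbme(d, fit_random=False, seed=0)
        assert fit.beta0 == pytest.approx(-11.7, abs=0.8)
        assert fit.beta1 == pytest.approx(0.55, abs=0.15)
        assert fit.beta2 == pytest.approx(2.0, abs=0.1)
        assert fit.theta == pytest.approx(5.0, rel=0.25)

    def test_all_zero_deaths_error(self):
        d = simulate_nb_transitions((-30.0, 0.5, 1.0), theta=5.0, n=30, seed=0)
        d["deaths_count"] = 0
        with pytest.raises(ValueError, match="no mortality signal"):
            fit_mortality_nbme(d)

    def test_theta_fixed_huge_reproduces_poisson_glm(self):
        """NB with theta pinned very large equals a Poisson GLM on
        Poisson-generated counts."""
        rng = np.random.default_rng(4)
        d = simulate_nb_transitions((-11.7, 0.55, 2.0), theta=1e9, n=400, seed=7)
        fit = fit_mortality_nbme(d, fit_random=False, theta_fixed=1e8, seed=0)
        X = sm.add_constant(np.column_stack([np.log(d["dg0_cm"]), np.log(d["n0_ha"])]))
        off = np.log(d["dg1_cm"] - d["dg0_cm"])
        pois = sm.GLM(d["deaths_count"], X, family=sm.families.Poisson(), offset=off).fit()
        assert fit.beta0 == pytest.approx(pois.params.iloc[0], abs=1e-3)
        assert fit.beta1 == pytest.approx(pois.params.iloc[1], abs=1e-3)
        assert fit.beta2 == pytest.approx(pois.params.iloc[2], abs=1e-3)
        assert abs(fit.loglik - pois.llf) < 1e-2

    def test_deaths_from_transitions_rounding(self):
        tr = pd.DataFrame([dict(plot_id="A", N0=1000.0, N1=940.0, dg0=15.0, dg1=18.0,
                                delta_n=60.0, delta_dg=3.0)])
        d = deaths_from_transitions(tr, 2500.0)
        assert d["deaths_count"].iloc[0] == 15  # 60/ha on a quarter hectare


class TestTrajectory:
    TRUTH = (7.2, -0.62, 0.04, 0.8)

    def _series(self, rng, n_plots=30, noise=0.02):
        a0, a1, a2, a3 = self.TRUTH
        rows = []
        for i in range(n_plots):
            lnN1 = rng.uniform(7.4, 8.2)
            lndg1 = a0 + a1 * lnN1 - rng.uniform(0.15, 0.55)
            lnN = lnN1 - np.linspace(0, rng.uniform(0.8, 1.6), 5)
            mu = trajectory_mean(self.TRUTH, lnN, lnN1, lndg1)
            lndg = mu.copy()
            lndg[1:] += rng.normal(0, noise, 4)
            rows.append(dict(plot_id=f"p{i:03d}", occasion=0,
                             n_ha=np.exp(lnN1), dg_cm=np.exp(lndg1)))
            for j in range(1, 5):
                rows.append(dict(plot_id=f"p{i:03d}", occasion=j,
                                 n_ha=np.exp(lnN[j]), dg_cm=np.exp(lndg[j])))
        return pd.DataFrame(rows)

    def test_alpha2_zero_degenerates_to_line(self):
        lnN = np.linspace(7.0, 8.0, 5)
        mu = trajectory_mean((7.2, -0.62, 0.0, 0.8), lnN, 8.0, 2.0)
        assert mu == pytest.approx(7.2 - 0.62 * lnN)

    def test_anchor_displacement_structure(self):
        """At the first measurement the displacement term is the full
        (a0 a2)^2 / gap; it decays as density falls below N1st."""
        a = (7.2, -0.62, 0.04, 0.8)
        lnN1, lndg1 = 8.0, 7.2 - 0.62 * 8.0 - 0.3
        at_first = trajectory_mean(a, np.array([lnN1]), lnN1, lndg1)[0]
        later = trajectory_mean(a, np.array([lnN1 - 1.0]), lnN1, lndg1)[0]
        line_first = a[0] + a[1] * lnN1
        line_later = a[0] + a[1] * (lnN1 - 1.0)
        assert line_first - at_first == pytest.approx((a[0] * a[2]) ** 2 / 0.3, rel=1e-9)
        assert (line_later - later) < (line_first - at_first)

    def test_noise_free_exact_recovery(self):
        fit = fit_trajectory_nlme(self._series(np.random.default_rng(5), noise=0.0), seed=0)
        assert fit.alpha0 == pytest.approx(7.2, abs=1e-6)
        assert fit.alpha1 == pytest.approx(-0.62, abs=1e-6)
        assert abs(fit.alpha2) == pytest.approx(0.04, abs=1e-6)
        assert fit.alpha3 == pytest.approx(0.8, abs=1e-5)

    def test_fitted_curve_monotone(self):
        fit = fit_trajectory_nlme(self._series(np.random.default_rng(6)), seed=0)
        lnN = np.linspace(8.0, 6.5, 40)
        mu = trajectory_mean((fit.alpha0, fit.alpha1, fit.alpha2, fit.alpha3),
                             lnN, 8.0, fit.alpha0 + fit.alpha1 * 8.0 - 0.3)
        assert np.all(np.diff(mu) > 0)  # dg grows as N declines

    def test_needs_remeasured_plots(self):
        plots = pd.DataFrame(plot_rows("A", [3000], [14]) + plot_rows("B", [2500], [16]))
        with pytest.raises(ValueError, match=">= 2 plots"):
            fit_trajectory_nlme(plots)
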