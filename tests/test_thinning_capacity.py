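import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selfthin.static_frontier import FrontierFit, QuantileFit
from selfthin.dynamic_models import TrajectoryFit
from selfthin.thinning_capacity import (
    ThinningLine,
    compact_letter_display,
    fit_capacity_model,
    line_from_frontier,
    line_from_ode_params,
    line_from_trajectory,
    line_from_upper_ci,
    predict_nmax,
    scheffe_compare,
    screen_bioclim,
)


def qfit(b0, b1, se0=0.2, se1=0.05):
    return QuantileFit(tau=0.95, beta0_tau=b0, beta1_tau=b1, se_beta0=se0,
                       se_beta1=se1, var_u0=0.01, sigma_ala=0.05, loglik=0.0)


class TestLineDerivations:
    def test_upper_ci_shift(self):
        line = line_from_upper_ci(qfit(11.0, -1.5, se0=0.2), "S-P-LQMM")
        assert line.intercept == pytest.approx(11.392)
        assert line.slope == -1.5
        assert line.intercept_unshifted == 11.0

    def test_zero_se_degenerate_ci(self):
        line = line_from_upper_ci(qfit(11.0, -1.5, se0=0.0), "S-P-LQMM")
        assert line.intercept == 11.0

    def test_smaller_alpha_shifts_less(self):
        wide = line_from_upper_ci(qfit(11.0, -1.5), "S-P-LQMM", alpha=0.05)
        narrow = line_from_upper_ci(qfit(11.0, -1.5), "S-P-LQMM", alpha=0.32)
        mult = stats.norm.ppf(1 - 0.32 / 2)
        assert narrow.intercept == pytest.approx(11.0 + mult * 0.2)
        assert narrow.intercept < wide.intercept

    def test_missing_se_error(self):
        with pytest.raises(ValueError, match="SE"):
            line_from_upper_ci(qfit(11.0, -1.5, se0=np.nan), "S-P-LQMM")

    def test_frontier_passthrough(self):
        fit = FrontierFit(beta0=11.7, beta1=-1.33, se_beta0=0.1, se_beta1=0.03,
                          sigma_v=0.08, sigma_u=0.2, var_u0re=0.01, loglik=0.0)
        line = line_from_frontier(fit)
        assert (line.intercept, line.slope) == (11.7, -1.33)

    @pytest.mark.parametrize(
        "beta, expect",
        [((0.0, 1.0, 2.0), (np.log(2.0), -2.0)),
         ((0.0, 0.5, 2.5), (None, -1.0))],
    )
    def test_ode_attractor_examples(self, beta, expect):
        line = line_from_ode_params(*beta)
        assert line.slope == pytest.approx(expect[1])
        if expect[0] is not None:
            assert line.intercept == pytest.approx(expect[0])

    def test_ode_domain_errors_name_bound(self):
        with pytest.raises(ValueError, match="beta2 > 1"):
            line_from_ode_params(0.0, 1.0, 0.8)
        with pytest.raises(ValueError, match="beta1 > -1"):
            line_from_ode_params(0.0, -1.5, 2.0)

    def test_trajectory_inversion_and_round_trip(self):
        fit = TrajectoryFit(alpha0=7.2, alpha1=-0.62, alpha2=0.0, alpha3=1.0,
                            ses=(0,) * 4, var_u0=0, sigma_e=0, loglik=0, bic=0)
        line = line_from_trajectory(fit)
        assert line.intercept == pytest.approx(7.2 / 0.62)
        assert line.slope == pytest.approx(-1.0 / 0.62)
        # round trip: the forward line of the inverted line returns (a0, a1)
        a1 = 1.0 / line.slope
        a0 = -line.intercept * a1
        assert (a0, a1) == (pytest.approx(7.2), pytest.approx(-0.62))

    def test_trajectory_alpha1_zero_error(self):
        fit = TrajectoryFit(alpha0=7.2, alpha1=0.0, alpha2=0.0, alpha3=1.0,
                            ses=(0,) * 4, var_u0=0, sigma_e=0, loglik=0, bic=0)
        with pytest.raises(ValueError, match="alpha1"):
            line_from_trajectory(fit)


class TestPredictNmax:
    @pytest.mark.parametrize(
        "b0, b1, expect",
        [(12.257, -1.4742, 1787.07), (11.4787, -1.2741, 1567.61)],
    )
    def test_reference_lines(self, b0, b1, expect):
        line = ThinningLine("S", b0, b1, "upper-CI")
        assert predict_nmax(line, 25.4) == pytest.approx(expect, abs=0.5)

    def test_unit_dbase_identity(self):
        line = ThinningLine("S", 7.3, -1.6, "frontier")
        assert predict_nmax(line, 1.0) == pytest.approx(np.exp(7.3))

    def test_monotone_decreasing_in_dbase(self):
        line = ThinningLine("S", 12.0, -1.5, "frontier")
        vals = [predict_nmax(line, d) for d in (10, 20, 30, 40)]
        assert np.all(np.diff(vals) < 0)

    def test_plot_effect_shifts_capacity(self):
        line = ThinningLine("S", 12.0, -1.5, "frontier")
        assert predict_nmax(line, 25.4, plot_effect=0.1) == pytest.approx(
            predict_nmax(line, 25.4) * np.exp(0.1))


class TestScheffe:
    def _estimates(self, means, n=12, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        frames = [pd.DataFrame(dict(strategy=f"S{i}", plot_id=[f"p{j}" for j in range(n)],
                                    sdi_max=rng.normal(m, sd, n)))
                  for i, m in enumerate(means)]
        return pd.concat(frames, ignore_index=True)

    def test_equal_means_share_a_letter(self):
        table, contrasts = scheffe_compare(self._estimates([10.0] * 4))
        assert (table["letters"] == "a").all()
        assert not contrasts["significant"].any()

    def test_separated_groups_get_distinct_letters(self):
        table, _ = scheffe_compare(self._estimates([10.0, 30.0], sd=1.0))
        letters = dict(zip(table["strategy"], table["letters"]))
        assert set(letters["S0"]).isdisjoint(set(letters["S1"]))

    def test_zero_variance_everywhere_errors(self):
        est = self._estimates([10.0, 20.0], sd=0.0)
        with pytest.raises(ValueError, match="zero within-group variance"):
            scheffe_compare(est)

    def test_needs_two_strategies(self):
        with pytest.raises(ValueError, match=">= 2 strategies"):
            scheffe_compare(self._estimates([10.0]))

    def test_cld_insert_and_absorb_pattern(self):
        # A > B > C with A!=C only: A and C must not share; B bridges both
        sig = {("A", "C"): True, ("C", "A"): True}
        letters = compact_letter_display(["A", "B", "C"], sig)
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])


class TestCapacityModel:
    def _capacity_data(self, rng, n=200, vertex=0.5, noise=0.0, bio14_coef=3.0):
        pba = rng.uniform(0.2, 1.0, n)
        shannon = rng.uniform(0.05, 1.8, n)
        bio14 = rng.normal(60, 25, n)
        sdi = (800 + 120 * shannon + bio14_coef * bio14
               + 900 * pba - 900 * pba**2 + rng.normal(0, noise, n))
        cov = pd.DataFrame(dict(plot_id=[f"p{i}" for i in range(n)],
                                shannon=shannon, bio14=bio14, pba=pba))
        for j in range(1, 20):
            if j != 14:
                cov[f"bio{j}"] = rng.normal(0, 1, n)
        cap = pd.DataFrame(dict(plot_id=cov["plot_id"], sdi_max=sdi))
        return cap, cov

    def test_noise_free_exact_recovery(self):
        cap, cov = self._capacity_data(np.random.default_rng(0))
        fit = fit_capacity_model(cap, cov)
        assert fit.theta == pytest.approx([800, 120, 3.0, 900, -900], abs=1e-6)
        assert fit.rel_rmse == pytest.approx(0.0, abs=1e-8)

    def test_pba_vertex_recovered(self):
        cap, cov = self._capacity_data(np.random.default_rng(1), noise=40.0)
        fit = fit_capacity_model(cap, cov)
        assert fit.pba_optimum == pytest.approx(0.5, abs=0.05)

    def test_rank_deficient_design_reports_aliased(self):
        cap, cov = self._capacity_data(np.random.default_rng(2))
        with pytest.raises(ValueError, match="aliased"):
            fit_capacity_model(cap, cov, terms=("shannon", "shannon"))

    def test_screening_finds_bio14(self):
        cap, cov = self._capacity_data(np.random.default_rng(3), noise=30.0)
        table = screen_bioclim(cap, cov)
        assert table.iloc[0]["predictor"] == "bio14"
        assert len(table) == 19

    def test_screening_single_candidate(self):
        cap, cov = self._capacity_data(np.random.default_rng(4))
        table = screen_bioclim(cap, cov, candidates=["bio14"])
        assert len(table) == 1

    def test_constant_covariate_skipped(self):
        cap, cov = self._capacity_data(np.random.default_rng(5))
        cov["bio3"] = 7.0
        table = screen_bioclim(cap, cov)
        row = table[table["predictor"] == "bio3"].iloc[0]
        assert "skipped" in row["note"] and np.isinf(row["bic"])
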