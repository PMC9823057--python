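"""FIML likelihood, five-model fits, LRTs and profile confidence intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinvc.biometric import (
    N_FREE_PARAMS,
    fit_ace,
    fit_ace_stats,
    fit_saturated,
    group_stats,
    lrt,
    model_battery,
    neg2ll_group,
    pair_loglik,
    profile_ci,
    profile_neg2ll,
    split_groups,
)
from twinvc.power import simulate_design
from twinvc.simulate import TwinCohortSpec, simulate_cohort

LOG_2PI = np.log(2 * np.pi)


class TestPairLoglik:
    def test_standard_bivariate_normal_at_origin(self):
        assert pair_loglik(0.0, 0.0, (0.0, 0.0), np.eye(2)) == pytest.approx(-LOG_2PI)

    def test_three_pair_fiml_matches_density_formulas(self):
        mean = (0.3, -0.1)
        cov = np.array([[1.2, 0.5], [0.5, 0.9]])
        pairs = [(0.4, 0.2), (np.nan, -0.7), (1.1, np.nan)]
        expected = (
            stats.multivariate_normal(mean, cov).logpdf([0.4, 0.2])
            + stats.norm(-0.1, np.sqrt(0.9)).logpdf(-0.7)
            + stats.norm(0.3, np.sqrt(1.2)).logpdf(1.1)
        )
        total = sum(pair_loglik(a, b, mean, cov) for a, b in pairs)
        assert total == pytest.approx(expected, abs=1e-12)

    def test_degenerate_covariance_limit_is_minus_infinity(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert pair_loglik(0.5, -0.5, (0.0, 0.0), cov) == -np.inf

    def test_both_missing_contributes_zero(self):
        assert pair_loglik(np.nan, np.nan, (0.0, 0.0), np.eye(2)) == 0.0

    def test_group_statistics_reproduce_pairwise_sum(self):
        rng = np.random.default_rng(3)
        y1 = rng.standard_normal(50)
        y2 = 0.6 * y1 + 0.8 * rng.standard_normal(50)
        y1[:5] = np.nan
        y2[5:9] = np.nan
        g = group_stats(y1, y2)
        m, cov = (0.1, -0.2), np.array([[1.3, 0.4], [0.4, 1.1]])
        direct = -2.0 * sum(pair_loglik(a, b, m, cov) for a, b in zip(y1, y2))
        agg = neg2ll_group(g, m[0], m[1], cov[0, 0], cov[1, 1], cov[0, 1])
        assert agg == pytest.approx(direct, abs=1e-9)


class TestSaturated:
    def test_complete_data_ml_equals_sample_moments(self, toy_pairs):
        fit = fit_saturated(toy_pairs, "y", "2group")
        for zyg in ("MZ", "DZ"):
            sub = toy_pairs[toy_pairs["zygosity"] == zyg]
            y1, y2 = sub["y_1"].to_numpy(), sub["y_2"].to_numpy()
            n = len(sub)
            assert fit.parameters[f"{zyg}.mean1"] == pytest.approx(y1.mean(), abs=1e-6)
            assert fit.parameters[f"{zyg}.mean2"] == pytest.approx(y2.mean(), abs=1e-6)
            assert fit.parameters[f"{zyg}.var1"] == pytest.approx(y1.var(), abs=1e-6)
            assert fit.parameters[f"{zyg}.var2"] == pytest.approx(y2.var(), abs=1e-6)
            cov_n = ((y1 - y1.mean()) * (y2 - y2.mean())).sum() / n
            assert fit.parameters[f"{zyg}.cov"] == pytest.approx(cov_n, abs=1e-6)

    def test_free_parameter_counts(self, toy_pairs):
        assert fit_saturated(toy_pairs, "y", "2group").n_free_params == 10
        assert fit_saturated(toy_pairs, "y", "4group").n_free_params == 20
        assert N_FREE_PARAMS == {
            "sat2": 10, "ace2": 4, "sat4": 20, "ace4_free": 8, "ace4_equal": 5
        }

    def test_minus2ll_is_self_consistent_with_pair_loglik(self, toy_pairs):
        fit = fit_saturated(toy_pairs, "y", "2group")
        total = 0.0
        for zyg in ("MZ", "DZ"):
            sub = toy_pairs[toy_pairs["zygosity"] == zyg]
            p = fit.parameters
            mean = (p[f"{zyg}.mean1"], p[f"{zyg}.mean2"])
            cov = np.array(
                [[p[f"{zyg}.var1"], p[f"{zyg}.cov"]],
                 [p[f"{zyg}.cov"], p[f"{zyg}.var2"]]]
            )
            total += sum(
                pair_loglik(a, b, mean, cov)
                for a, b in zip(sub["y_1"], sub["y_2"])
            )
        assert fit.minus2LL == pytest.approx(-2.0 * total, abs=1e-8)

    def test_underfilled_group_is_named(self, toy_pairs):
        broken = toy_pairs.copy()
        broken.loc[broken["zygosity"] == "DZ", "y_2"] = np.nan
        broken.loc[broken["zygosity"] == "DZ", "y_1"] = np.nan
        with pytest.raises(Exception, match="DZ"):
            fit_saturated(broken, "y", "2group")

    def test_fiml_uses_half_pairs(self, toy_pairs):
        partial = toy_pairs.copy()
        partial.loc[partial.index[:8], "y_2"] = np.nan
        fit = fit_saturated(partial, "y", "2group")
        assert fit.converged
        assert sum(fit.n_pairs_by_group.values()) == len(toy_pairs)


class TestAce:
    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(31)
        groups = simulate_design(rng, 5000, 5000, 0.7, 0.45)
        _, est = fit_ace_stats(groups)
        e = est["overall"]
        # sampling SD of each share is ~0.02 at this size
        assert e.a2 == pytest.approx(0.5, abs=0.07)
        assert e.c2 == pytest.approx(0.2, abs=0.06)
        assert e.e2 == pytest.approx(0.3, abs=0.03)
        assert e.a2 + e.c2 + e.e2 == pytest.approx(1.0, abs=1e-8)

    def test_null_a_estimate_near_zero(self):
        rng = np.random.default_rng(37)
        groups = simulate_design(rng, 20000, 20000, 0.4, 0.4)
        _, est = fit_ace_stats(groups)
        assert abs(est["overall"].a2) < 0.05  # 3 MC SEs at this size

    def test_falconer_closed_form_oracle_on_weight_correlations(self):
        rng = np.random.default_rng(41)
        groups = simulate_design(rng, 100000, 100000, 0.89, 0.46)
        _, est = fit_ace_stats(groups)
        assert est["overall"].a2 == pytest.approx(2 * (0.89 - 0.46), abs=0.01)

    def test_negative_c_is_annotated(self):
        rng = np.random.default_rng(43)
        groups = simulate_design(rng, 5000, 5000, 0.7, 0.25)  # rDZ < rMZ/2
        _, est = fit_ace_stats(groups)
        assert est["overall"].C < 0
        assert "non-additive" in est["overall"].note

    def test_ace2_never_beats_sat2(self, medium_cohort):
        ace, _ = fit_ace(medium_cohort, "y", "2group")
        sat = fit_saturated(medium_cohort, "y", "2group")
        assert ace.minus2LL >= sat.minus2LL - 1e-8

    def test_likelihood_invariant_to_twin_relabeling(self, medium_cohort):
        swapped = medium_cohort.rename(columns={"y_1": "y_2", "y_2": "y_1"})
        f1, _ = fit_ace(medium_cohort, "y", "2group")
        f2, _ = fit_ace(swapped, "y", "2group")
        assert f1.minus2LL == pytest.approx(f2.minus2LL, abs=1e-6)


class TestLrt:
    def test_model_compared_with_itself(self, toy_pairs):
        fit = fit_saturated(toy_pairs, "y", "2group")
        stat, df, p = lrt(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_degrees_of_freedom_arithmetic(self, medium_cohort):
        sat2 = fit_saturated(medium_cohort, "y", "2group")
        ace2, _ = fit_ace(medium_cohort, "y", "2group")
        assert lrt(ace2, sat2)[1] == 6
        free, _ = fit_ace(medium_cohort, "y", "4group", equate_sex=False)
        equal, _ = fit_ace(medium_cohort, "y", "4group", equate_sex=True)
        assert lrt(equal, free)[1] == 3

    def test_null_lrt_statistic_is_chi_square_six(self):
        # data generated under ace2 (equal means/variances across order and
        # zygosity): the ace2-vs-sat2 statistic should follow chi2(6)
        stats_out = []
        for child in np.random.SeedSequence(47).spawn(400):
            rng = np.random.default_rng(child)
            groups = simulate_design(rng, 120, 120, 0.6, 0.4)
            sat_m2ll = 0.0
            for zyg, g in groups.items():
                n = g.n
                m1, m2 = g.s1 / n, g.s2 / n
                v1 = g.q11 / n - m1 * m1
                v2 = g.q22 / n - m2 * m2
                c = g.q12 / n - m1 * m2
                sat_m2ll += neg2ll_group(g, m1, m2, v1, v2, c)
            ace, _ = fit_ace_stats(groups)
            stats_out.append(ace.minus2LL - sat_m2ll)
        ks = stats.kstest(stats_out, stats.chi2(6).cdf)
        assert ks.pvalue > 0.01

    def test_sex_heterogeneity_pvalues_uniform_under_homogeneity(self):
        pvals = []
        for child in np.random.SeedSequence(53).spawn(300):
            rng = np.random.default_rng(child)
            groups = {}
            for sex in ("M", "F"):
                g = simulate_design(rng, 100, 100, 0.6, 0.4)
                groups[f"MZ_{sex}"] = g["MZ"]
                groups[f"DZ_{sex}"] = g["DZ"]
            free, _ = fit_ace_stats(groups, "4group", equate_sex=False)
            equal, _ = fit_ace_stats(groups, "4group", equate_sex=True)
            pvals.append(lrt(equal, free)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestProfileCI:
    def test_interval_contains_point_estimate(self, medium_cohort):
        fit, est = fit_ace(medium_cohort, "y", "2group")
        for comp in ("a2", "c2", "e2"):
            lo, hi = profile_ci(fit, comp)
            point = getattr(est["overall"], comp)
            assert lo < point < hi

    def test_bounds_match_dense_grid_profile(self):
        rng = np.random.default_rng(59)
        groups = simulate_design(rng, 80, 80, 0.7, 0.45)
        fit, est = fit_ace_stats(groups)
        lo, hi = profile_ci(fit, "a2")
        crit = stats.chi2.ppf(0.95, 1)
        point = est["overall"].a2
        grid = np.arange(point - 1.2, point + 1.2, 0.004)
        excess = np.array(
            [profile_neg2ll(fit, "a2", s) - fit.minus2LL for s in grid]
        )
        inside = np.nonzero(excess <= crit)[0]
        i0, i1 = inside.min(), inside.max()

        def crossing(ia, ib):
            x1, x2, y1, y2 = grid[ia], grid[ib], excess[ia], excess[ib]
            return x1 + (crit - y1) * (x2 - x1) / (y2 - y1)

        assert lo == pytest.approx(crossing(i0 - 1, i0), abs=1e-3)
        assert hi == pytest.approx(crossing(i1 + 1, i1), abs=1e-3)


class TestBattery:
    def test_row_schema_contract(self, medium_cohort):
        row = model_battery(medium_cohort, "y", by_sex_ci=False)
        assert row["status"] == "ok"
        m2lls = [row[k] for k in (
            "m2ll_sat2", "m2ll_ace2", "m2ll_sat4", "m2ll_ace4_free",
            "m2ll_ace4_equal")]
        assert len(m2lls) == 5 and all(np.isfinite(v) for v in m2lls)
        assert 0 <= row["p_assumptions"] <= 1
        assert 0 <= row["p_sex_het"] <= 1

    def test_battery_is_deterministic(self, medium_cohort):
        r1 = model_battery(medium_cohort, "y", by_sex_ci=False)
        r2 = model_battery(medium_cohort, "y", by_sex_ci=False)
        assert r1 == r2

    def test_battery_isolates_failures(self, medium_cohort):
        broken = medium_cohort.copy()
        broken["y_1"] = np.nan
        row = model_battery(broken, "y")
        assert row["status"].startswith("error:")
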