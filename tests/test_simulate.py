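"""Synthetic-cohort generator: covariance structure, artifacts, determinism."""

import numpy as np
import pandas as pd
import pytest

from twinvc.preprocess import build_design, preprocess_table
from twinvc.simulate import TwinCohortSpec, inject_artifacts, simulate_cohort


def _pair_r(table, zyg):
    sub = table[table["zygosity"] == zyg]
    return float(np.corrcoef(sub["y_1"], sub["y_2"])[0, 1])


def test_same_seed_same_spec_is_bit_identical():
    spec = TwinCohortSpec(n_mz_pairs=200, n_dz_pairs=150, missing_rate=0.05,
                          outlier_rate=0.02, seed=9)
    t1 = simulate_cohort(spec)
    t2 = simulate_cohort(TwinCohortSpec(n_mz_pairs=200, n_dz_pairs=150,
                                        missing_rate=0.05, outlier_rate=0.02, seed=9))
    pd.testing.assert_frame_equal(t1, t2)


def test_independent_case_has_zero_twin_correlations():
    spec = TwinCohortSpec(n_mz_pairs=20000, n_dz_pairs=20000, var_A=0.0,
                          var_C=0.0, var_E=1.0, fixed_effects={}, seed=3)
    table = simulate_cohort(spec)
    se = 1.0 / np.sqrt(20000)
    assert abs(_pair_r(table, "MZ")) < 3 * se
    assert abs(_pair_r(table, "DZ")) < 3 * se


def test_twin_correlations_match_closed_form_expectations():
    # standardized-scale expectations: rMZ = A + C, rDZ = A/2 + C
    spec = TwinCohortSpec(n_mz_pairs=50000, n_dz_pairs=50000, var_A=0.5,
                          var_C=0.2, var_E=0.3, fixed_effects={}, seed=4)
    table = simulate_cohort(spec)
    for zyg, r_true in (("MZ", 0.70), ("DZ", 0.45)):
        se = (1 - r_true**2) / np.sqrt(50000)
        assert abs(_pair_r(table, zyg) - r_true) < 3 * se


def test_empirical_pair_covariance_error_shrinks_with_n():
    errors = {}
    for n in (2000, 32000):
        spec = TwinCohortSpec(n_mz_pairs=n, n_dz_pairs=0, var_A=0.5, var_C=0.2,
                              var_E=0.3, fixed_effects={}, seed=5)
        table = simulate_cohort(spec)
        emp = float(np.cov(table["y_1"], table["y_2"])[0, 1])
        errors[n] = abs(emp - 0.7)
        # root-n band around the true MZ covariance A + C = 0.7
        assert errors[n] < 4.0 * 1.1 / np.sqrt(n)


def test_nonpositive_definite_covariance_names_offending_group():
    spec = TwinCohortSpec(n_mz_pairs=10, n_dz_pairs=10, var_A=0.5, var_C=-0.5,
                          var_E=0.2)
    with pytest.raises(ValueError, match="DZ"):
        simulate_cohort(spec)


def test_fixed_effects_recoverable_by_ols():
    beta = {"intercept": 1.0, "sex_F": 0.3, "age": 0.02, "race_Black": -0.2,
            "race_Hispanic": 0.1, "race_Asian": 0.0, "race_Other": 0.05,
            "site_CUB": 0.15, "site_VCU": -0.1, "site_WUSTL": 0.05}
    spec = TwinCohortSpec(n_mz_pairs=4000, n_dz_pairs=4000, fixed_effects=beta,
                          seed=6)
    table = simulate_cohort(spec)
    import statsmodels.api as sm

    covs = table[["sex", "age_months", "race", "site"]]
    X = build_design(pd.concat([covs, covs], ignore_index=True))
    y = np.concatenate([table["y_1"], table["y_2"]])
    keep = [c for c in X.columns if c == "intercept" or X[c].std() > 0]
    fit = sm.OLS(y, X[keep]).fit()
    for term in keep:
        true = beta.get(term, 0.0)
        assert abs(fit.params[term] - true) < 3 * fit.bse[term] + 1e-12, term


def test_inject_artifacts_zero_rates_is_identity(medium_cohort):
    out = inject_artifacts(medium_cohort, missing_rate=0.0, outlier_rate=0.0, seed=1)
    pd.testing.assert_frame_equal(
        out.drop(columns=["y_1_outlier", "y_2_outlier"]), medium_cohort
    )
    assert not out["y_1_outlier"].any() and not out["y_2_outlier"].any()


def test_missingness_count_is_binomial():
    spec = TwinCohortSpec(n_mz_pairs=2500, n_dz_pairs=2500, seed=8)
    table = simulate_cohort(spec)
    out = inject_artifacts(table, missing_rate=0.1, seed=12)
    n_missing = int(out[["y_1", "y_2"]].isna().sum().sum())
    expected, sd = 1000.0, np.sqrt(10000 * 0.1 * 0.9)
    assert abs(n_missing - expected) < 3 * sd


def test_injected_six_sd_outliers_are_masked_at_threshold_four():
    spec = TwinCohortSpec(n_mz_pairs=1500, n_dz_pairs=1500, seed=13)
    table = simulate_cohort(spec)
    out = inject_artifacts(table, outlier_rate=0.005, outlier_magnitude=6.0, seed=14)
    n_out = int(out["y_1_outlier"].sum() + out["y_2_outlier"].sum())
    assert n_out > 0
    prepped, report = preprocess_table(out, ["y"], threshold=4.0)
    flagged_masked = sum(
        int((out[f"y_{i}_outlier"] & prepped[f"y_res_{i}"].isna()).sum())
        for i in (1, 2)
    )
    assert flagged_masked == n_out
    assert report["y"]["n_masked"] >= n_out


def test_negative_outlier_magnitude_rejected(medium_cohort):
    with pytest.raises(ValueError, match="magnitude"):
        inject_artifacts(medium_cohort, outlier_rate=0.1, outlier_magnitude=-1.0)


def test_spec_yaml_round_trip():
    spec = TwinCohortSpec(n_mz_pairs=11, n_dz_pairs=13, var_A=0.4, seed=99)
    assert TwinCohortSpec.from_yaml(spec.to_yaml()) == spec
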