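"""Covariate residualization, standardization and outlier masking.

The pre-modelling pipeline: regress sex, age, race (four dummies vs the
White reference) and site (three dummies vs the UMN reference) out of each
phenotype by ordinary least squares over individual twins, standardize the
residuals, and set values more than ``threshold`` (default 4) standard
deviations from the mean to missing. The SD is computed once, before
masking, with the n-1 divisor; masking uses the strict inequality
``|z| > threshold`` and is applied a single time (no re-standardization).

Within-pair dependence is deliberately ignored here — both twins enter as
plain rows — because the dependence is modelled downstream in the
likelihood, not in the fixed-effect adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import RACE_LEVELS, SITE_LEVELS

DESIGN_TERMS = (
    "intercept",
    "sex_F",
    "age",
    *(f"race_{lvl}" for lvl in RACE_LEVELS[1:]),
    *(f"site_{lvl}" for lvl in SITE_LEVELS[1:]),
)


@dataclass
class CovariateModel:
    """Fitted fixed-effect adjustment model (for audit)."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    n_used: int


@dataclass
class ResidualizedPhenotype:
    """Standardized residuals after one-shot outlier masking."""

    values: np.ndarray
    n_masked: int
    mask_threshold: float
    sd_used: float
    mean_used: float


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Design matrix with the fixed reference codings.

    ``covariates`` needs columns ``sex`` (M/F), ``age_months``, ``race`` and
    ``site``; category levels outside the declared sets raise.
    """
    for col in ("sex", "age_months", "race", "site"):
        if col not in covariates.columns:
            raise KeyError(f"covariate column {col!r} missing")
    for col, levels in (("sex", ("M", "F")), ("race", RACE_LEVELS), ("site", SITE_LEVELS)):
        seen = set(covariates[col].dropna().unique())
        unknown = seen - set(levels)
        if unknown:
            raise ValueError(f"unseen {col} level(s): {sorted(unknown)}")

    X = pd.DataFrame(index=covariates.index)
    X["intercept"] = 1.0
    X["sex_F"] = (covariates["sex"] == "F").astype(float)
    X["age"] = covariates["age_months"].astype(float)
    for level in RACE_LEVELS[1:]:
        X[f"race_{level}"] = (covariates["race"] == level).astype(float)
    for level in SITE_LEVELS[1:]:
        X[f"site_{level}"] = (covariates["site"] == level).astype(float)
    # propagate missing covariates so those rows drop out of the fit
    covariate_missing = covariates[["sex", "age_months", "race", "site"]].isna().any(axis=1)
    X.loc[covariate_missing.to_numpy(), :] = np.nan
    return X


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.nonzero(diag <= tol)[0]]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


def residualize(
    values: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    drop_unused_terms: bool = True,
) -> tuple[np.ndarray, CovariateModel]:
    """OLS residuals of ``values`` against the covariate design.

    Rows with a missing phenotype or any missing covariate get a missing
    residual. Columns that are constant over the used rows (e.g. an empty
    race category in a small sample) are dropped from the design when
    ``drop_unused_terms`` so the fit stays full-rank; the fitted
    coefficients are returned for audit.
    """
    y = np.asarray(values, dtype=float)
    X = build_design(covariates)
    if len(y) != len(X):
        raise ValueError("values and covariates have different lengths")

    used = np.isfinite(y) & np.isfinite(X.to_numpy(float)).all(axis=1)
    Xu = X.loc[used]
    if drop_unused_terms:
        keep = [
            c
            for c in Xu.columns
            if c == "intercept" or float(Xu[c].std()) > 0.0
        ]
        Xu = Xu[keep]
    if used.sum() < Xu.shape[1] + 2:
        raise ValueError(
            f"need at least {Xu.shape[1] + 2} complete observations, have {int(used.sum())}"
        )
    _check_rank(Xu.to_numpy(float), list(Xu.columns))

    fit = sm.OLS(y[used], Xu.to_numpy(float)).fit()
    resid = np.full(len(y), np.nan)
    resid[used] = y[used] - Xu.to_numpy(float) @ fit.params
    model = CovariateModel(
        terms=tuple(Xu.columns),
        coefficients=dict(zip(Xu.columns, (float(b) for b in fit.params))),
        n_used=int(used.sum()),
    )
    return resid, model


def standardize_mask(
    residuals: np.ndarray | pd.Series, threshold: float = 4.0
) -> ResidualizedPhenotype:
    """Standardize residuals once, then mask values with ``|z| > threshold``.

    Mean and SD (n-1 divisor) are computed from the non-missing residuals
    before masking and are not recomputed afterwards, so the returned values
    have mean 0 and SD 1 over the pre-masking observed set.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    r = np.asarray(residuals, dtype=float)
    observed = np.isfinite(r)
    if observed.sum() < 2:
        raise ValueError("need at least 2 non-missing residuals")
    mean = float(r[observed].mean())
    sd = float(r[observed].std(ddof=1))
    if sd == 0.0:
        raise ValueError("constant phenotype: zero residual variance")
    z = np.full(len(r), np.nan)
    z[observed] = (r[observed] - mean) / sd
    mask = np.isfinite(z) & (np.abs(z) > threshold)
    z[mask] = np.nan
    return ResidualizedPhenotype(
        values=z,
        n_masked=int(mask.sum()),
        mask_threshold=float(threshold),
        sd_used=sd,
        mean_used=mean,
    )


def preprocess_table(
    table: pd.DataFrame,
    phenotypes: list[str],
    threshold: float = 4.0,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Residualize + standardize + mask each phenotype of a pair table.

    Both twins of each pair are stacked as individual rows (sharing the
    pair's covariates) for the adjustment; the standardized, masked values
    are written back as ``<name>_res_1`` / ``<name>_res_2`` columns.
    Returns the augmented table and a per-phenotype masking report.
    """
    out = table.copy()
    report: dict[str, dict[str, int]] = {}
    covs = table[["sex", "age_months", "race", "site"]]
    long_covs = pd.concat([covs, covs], ignore_index=True)
    n = len(table)
    for name in phenotypes:
        c1, c2 = f"{name}_1", f"{name}_2"
        if c1 not in table.columns or c2 not in table.columns:
            raise KeyError(f"phenotype columns {c1!r}/{c2!r} not in table")
        y = np.concatenate(
            [table[c1].to_numpy(float), table[c2].to_numpy(float)]
        )
        resid, _model = residualize(y, long_covs)
        rp = standardize_mask(resid, threshold=threshold)
        out[f"{name}_res_1"] = rp.values[:n]
        out[f"{name}_res_2"] = rp.values[n:]
        report[name] = {
            "n_masked": rp.n_masked,
            "n_missing_input": int(np.sum(~np.isfinite(y))),
        }
    return out, report
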