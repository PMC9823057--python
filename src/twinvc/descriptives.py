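"""Zygosity- and sex-stratified twin correlations and Levene variance tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MIN_PAIRS_PER_STRATUM = 3


@dataclass
class CorrelationSummary:
    """Pearson twin correlations by zygosity (and optionally sex).

    Correlations for strata with fewer than three complete pairs are NaN
    and the reason is recorded in ``notes``.
    """

    r_mz: float
    r_dz: float
    r_mz_m: float = np.nan
    r_mz_f: float = np.nan
    r_dz_m: float = np.nan
    r_dz_f: float = np.nan
    n_pairs: dict[str, int] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)


@dataclass
class LeveneResult:
    statistic: float
    df_between: int
    df_within: int
    p_value: float
    groups: tuple[str, ...]


def _pair_columns(table: pd.DataFrame, phenotype: str) -> tuple[str, str]:
    c1, c2 = f"{phenotype}_1", f"{phenotype}_2"
    if c1 not in table.columns or c2 not in table.columns:
        raise KeyError(f"phenotype columns {c1!r}/{c2!r} not in table")
    return c1, c2


def _stratum_r(
    sub: pd.DataFrame, c1: str, c2: str, double_entry: bool
) -> tuple[float, int, str]:
    y1 = sub[c1].to_numpy(float)
    y2 = sub[c2].to_numpy(float)
    complete = np.isfinite(y1) & np.isfinite(y2)
    n = int(complete.sum())
    if n < MIN_PAIRS_PER_STRATUM:
        return np.nan, n, f"only {n} complete pairs (< {MIN_PAIRS_PER_STRATUM})"
    a, b = y1[complete], y2[complete]
    if double_entry:
        a, b = np.concatenate([a, b]), np.concatenate([b, a])
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return np.nan, n, "zero variance within stratum"
    return float(stats.pearsonr(a, b).statistic), n, ""


def twin_correlations(
    table: pd.DataFrame,
    phenotype: str,
    by_sex: bool = True,
    double_entry: bool = False,
) -> CorrelationSummary:
    """Pearson correlations between twin 1 and twin 2 over complete pairs.

    Twin order is taken as recorded; ``double_entry=True`` instead computes
    the double-entry (intraclass-style) correlation by stacking both
    orderings — off by default.
    """
    c1, c2 = _pair_columns(table, phenotype)
    strata: dict[str, pd.DataFrame] = {
        "MZ": table[table["zygosity"] == "MZ"],
        "DZ": table[table["zygosity"] == "DZ"],
    }
    if by_sex:
        for zyg in ("MZ", "DZ"):
            for sex in ("M", "F"):
                strata[f"{zyg}_{sex}"] = table[
                    (table["zygosity"] == zyg) & (table["sex"] == sex)
                ]
    results: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    notes: dict[str, str] = {}
    for key, sub in strata.items():
        r, n, note = _stratum_r(sub, c1, c2, double_entry)
        results[key] = r
        n_pairs[key] = n
        if note:
            notes[key] = note
    return CorrelationSummary(
        r_mz=results["MZ"],
        r_dz=results["DZ"],
        r_mz_m=results.get("MZ_M", np.nan),
        r_mz_f=results.get("MZ_F", np.nan),
        r_dz_m=results.get("DZ_M", np.nan),
        r_dz_f=results.get("DZ_F", np.nan),
        n_pairs=n_pairs,
        notes=notes,
    )


def levene(
    table: pd.DataFrame, phenotype: str, grouping: str = "zygosity"
) -> LeveneResult:
    """Classic (mean-centered) Levene homogeneity-of-variance test.

    Individual twins are stacked as observations; groups are zygosity
    (MZ/DZ) or zygosity x sex. Pair dependence is ignored, as in a plain
    one-way Levene F.
    """
    c1, c2 = _pair_columns(table, phenotype)
    if grouping == "zygosity":
        keys = ["MZ", "DZ"]
        masks = [table["zygosity"] == k for k in keys]
    elif grouping in ("zygosity_sex", "zygosity×sex"):
        keys = ["MZ_M", "MZ_F", "DZ_M", "DZ_F"]
        masks = [
            (table["zygosity"] == z) & (table["sex"] == s)
            for z, s in (("MZ", "M"), ("MZ", "F"), ("DZ", "M"), ("DZ", "F"))
        ]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    samples = []
    for key, mask in zip(keys, masks):
        vals = np.concatenate(
            [table.loc[mask, c1].to_numpy(float), table.loc[mask, c2].to_numpy(float)]
        )
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(
                f"group {key!r} has {len(vals)} non-missing values (< 2)"
            )
        samples.append(vals)
    stat, p = stats.levene(*samples, center="mean")
    df_between = len(samples) - 1
    df_within = int(sum(len(s) for s in samples)) - len(samples)
    return LeveneResult(
        statistic=float(stat),
        df_between=df_between,
        df_within=df_within,
        p_value=float(p),
        groups=tuple(keys),
    )
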