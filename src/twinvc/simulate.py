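"""Synthetic same-sex twin cohorts with ACE/ADE covariance structure.

Generates wide, one-row-per-pair tables whose phenotypes are bivariate
normal around a linear fixed-effect predictor (sex, age, race, site) with
the classical twin expectations:

* MZ pair covariance  A + C + D      (MZ twins share all genetic effects)
* DZ pair covariance  A/2 + C + D/4  (half the additive, a quarter of the
  dominance sharing)
* common total variance A + C + D + E

C may be negative (a familial residual), so covariance matrices are built
by explicit Cholesky factors and validated for positive definiteness per
zygosity group. Missingness and outlier contamination are injected in a
separate, separately seeded pass so each stage is reproducible on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

SITE_LEVELS: tuple[str, ...] = ("UMN", "CUB", "VCU", "WUSTL")
RACE_LEVELS: tuple[str, ...] = ("White", "Black", "Hispanic", "Asian", "Other")

#: cohort marginal frequencies emulating a four-site, population-ascertained
#: US twin sample of 9-10 year olds (site roughly balanced; race margins
#: about 66/14/10/0.2/10 percent).
DEFAULT_SITE_PROBS: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
DEFAULT_RACE_PROBS: tuple[float, ...] = (0.662, 0.142, 0.098, 0.002, 0.096)
DEFAULT_SEX_FRACTION_FEMALE: float = 0.565

#: table columns written by :func:`simulate_cohort` (the documented header)
TABLE_COLUMNS = (
    "pair_id",
    "zygosity",
    "sex",
    "site",
    "age_months",
    "race",
    "y_1",
    "y_2",
)


def default_fixed_effects() -> dict[str, float]:
    """Modest, realistic covariate effects on the raw-trait scale.

    Keys follow the design-matrix naming used by :mod:`twinvc.preprocess`:
    ``intercept``, ``sex_F`` (female vs male), ``age`` (per month),
    ``race_<level>`` (vs White) and ``site_<level>`` (vs UMN).
    """
    return {
        "intercept": 0.0,
        "sex_F": 0.2,
        "age": 0.01,
        "race_Black": -0.10,
        "race_Hispanic": -0.05,
        "race_Asian": 0.0,
        "race_Other": -0.02,
        "site_CUB": 0.05,
        "site_VCU": -0.05,
        "site_WUSTL": 0.02,
    }


@dataclass
class TwinCohortSpec:
    """Full description of one synthetic cohort; same spec + seed gives a
    bit-identical table."""

    n_mz_pairs: int
    n_dz_pairs: int
    var_A: float = 0.5
    var_C: float = 0.2
    var_D: float = 0.0
    var_E: float = 0.3
    sex_fraction_female: float = DEFAULT_SEX_FRACTION_FEMALE
    fixed_effects: dict[str, float] = field(default_factory=default_fixed_effects)
    age_range: tuple[int, int] = (108, 131)
    site_probs: tuple[float, ...] = DEFAULT_SITE_PROBS
    race_probs: tuple[float, ...] = DEFAULT_RACE_PROBS
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0
    seed: int = 0

    def total_variance(self) -> float:
        return self.var_A + self.var_C + self.var_D + self.var_E

    def pair_covariance(self, zygosity: str) -> float:
        if zygosity == "MZ":
            return self.var_A + self.var_C + self.var_D
        if zygosity == "DZ":
            return 0.5 * self.var_A + self.var_C + 0.25 * self.var_D
        raise ValueError(f"unknown zygosity {zygosity!r}")

    def validate(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be >= 0")
        if self.var_A < 0 or self.var_D < 0:
            raise ValueError("var_A and var_D must be >= 0")
        if self.var_E <= 0:
            raise ValueError("var_E must be > 0")
        if self.total_variance() <= 0:
            raise ValueError("total variance must be > 0")
        for name, rate in (
            ("sex_fraction_female", self.sex_fraction_female),
            ("missing_rate", self.missing_rate),
            ("outlier_rate", self.outlier_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if self.outlier_magnitude < 0:
            raise ValueError("outlier_magnitude must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low <= high")
        total = self.total_variance()
        for zyg in ("MZ", "DZ"):
            cov = self.pair_covariance(zyg)
            # 2x2 exchangeable matrix [[T, cov], [cov, T]] is PD iff |cov| < T
            if abs(cov) >= total:
                raise ValueError(
                    f"implied {zyg} pair covariance matrix is not positive "
                    f"definite (total variance {total:g}, covariance {cov:g})"
                )

    # -- serialization -------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["site_probs"] = list(self.site_probs)
        d["race_probs"] = list(self.race_probs)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TwinCohortSpec":
        d = yaml.safe_load(text)
        for key in ("age_range", "site_probs", "race_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _bivariate_residuals(
    rng: np.random.Generator, n: int, total: float, cov: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n pairs from N(0, [[total, cov], [cov, total]]) via Cholesky."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    l11 = np.sqrt(total)
    l21 = cov / l11
    l22 = np.sqrt(total - l21 * l21)
    return l11 * z1, l21 * z1 + l22 * z2


def simulate_cohort(spec: TwinCohortSpec) -> pd.DataFrame:
    """Simulate one cohort of same-sex MZ and DZ pairs.

    Returns a wide table with one row per pair (columns ``TABLE_COLUMNS``).
    Age, race and site are shared by both members of a pair; sex is a
    pair-level attribute because only same-sex pairs are modelled.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_total = spec.n_mz_pairs + spec.n_dz_pairs
    zygosity = np.array(["MZ"] * spec.n_mz_pairs + ["DZ"] * spec.n_dz_pairs)
    sex = np.where(rng.random(n_total) < spec.sex_fraction_female, "F", "M")
    site = rng.choice(SITE_LEVELS, size=n_total, p=spec.site_probs)
    race = rng.choice(RACE_LEVELS, size=n_total, p=spec.race_probs)
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n_total)

    beta = spec.fixed_effects
    eta = np.full(n_total, float(beta.get("intercept", 0.0)))
    eta += np.where(sex == "F", float(beta.get("sex_F", 0.0)), 0.0)
    eta += float(beta.get("age", 0.0)) * age
    for level in RACE_LEVELS[1:]:
        eta += np.where(race == level, float(beta.get(f"race_{level}", 0.0)), 0.0)
    for level in SITE_LEVELS[1:]:
        eta += np.where(site == level, float(beta.get(f"site_{level}", 0.0)), 0.0)

    total = spec.total_variance()
    y1 = np.empty(n_total)
    y2 = np.empty(n_total)
    for zyg in ("MZ", "DZ"):
        idx = zygosity == zyg
        e1, e2 = _bivariate_residuals(rng, int(idx.sum()), total, spec.pair_covariance(zyg))
        y1[idx] = eta[idx] + e1
        y2[idx] = eta[idx] + e2

    table = pd.DataFrame(
        {
            "pair_id": [f"P{i:06d}" for i in range(n_total)],
            "zygosity": zygosity,
            "sex": sex,
            "site": site,
            "age_months": age,
            "race": race,
            "y_1": y1,
            "y_2": y2,
        }
    )
    if spec.missing_rate > 0 or spec.outlier_rate > 0:
        # independent stream so artifact injection is reproducible by itself
        artifact_seed = int(
            np.random.SeedSequence([spec.seed, 0x5EED]).generate_state(1)[0] % (2**31)
        )
        table = inject_artifacts(
            table,
            missing_rate=spec.missing_rate,
            outlier_rate=spec.outlier_rate,
            outlier_magnitude=spec.outlier_magnitude,
            seed=artifact_seed,
        )
    return table


def inject_artifacts(
    table: pd.DataFrame,
    missing_rate: float = 0.0,
    outlier_rate: float = 0.0,
    outlier_magnitude: float = 6.0,
    seed: int = 0,
    phenotype: str = "y",
) -> pd.DataFrame:
    """Set observed values missing and/or displace them to +-magnitude SD.

    Each observed phenotype value is independently set missing with
    ``missing_rate``; each surviving value is independently displaced to
    ``mean +- outlier_magnitude * SD`` (random sign; moments of the
    pre-injection observed values) with ``outlier_rate``. Displacements are
    flagged in ``<phenotype>_<i>_outlier`` columns.
    """
    for name, rate in (("missing_rate", missing_rate), ("outlier_rate", outlier_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    if outlier_magnitude < 0:
        raise ValueError("outlier_magnitude must be >= 0")

    cols = [f"{phenotype}_1", f"{phenotype}_2"]
    for col in cols:
        if col not in table.columns:
            raise KeyError(f"phenotype column {col!r} not in table")

    out = table.copy()
    rng = np.random.default_rng(seed)
    pooled = pd.concat([out[c] for c in cols]).to_numpy(float)
    pooled = pooled[np.isfinite(pooled)]
    mean = float(pooled.mean()) if pooled.size else 0.0
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 1.0

    for col in cols:
        values = out[col].to_numpy(float).copy()
        observed = np.isfinite(values)
        drop = observed & (rng.random(len(values)) < missing_rate)
        values[drop] = np.nan
        observed = np.isfinite(values)
        hit = observed & (rng.random(len(values)) < outlier_rate)
        signs = np.where(rng.random(len(values)) < 0.5, -1.0, 1.0)
        values[hit] = mean + signs[hit] * outlier_magnitude * sd
        out[col] = values
        out[f"{col}_outlier"] = hit
    return out


def write_cohort(table: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a twin-pair table as delimited text (comma default)."""
    table.to_csv(path, sep=sep, index=False)


def read_cohort(path, sep: str = ",") -> pd.DataFrame:
    """Read a twin-pair table written by :func:`write_cohort`."""
    return pd.read_csv(path, sep=sep)
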