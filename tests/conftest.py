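import numpy as np
import pandas as pd
import pytest

from twinvc.simulate import TwinCohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """Preprocess-ready cohort: 400 MZ + 400 DZ pairs, shares 0.5/0.2/0.3."""
    spec = TwinCohortSpec(n_mz_pairs=400, n_dz_pairs=400, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def toy_pairs() -> pd.DataFrame:
    """Small complete-data pair table for exact-arithmetic checks."""
    rng = np.random.default_rng(7)
    n = 60
    zyg = np.array(["MZ"] * (n // 2) + ["DZ"] * (n // 2))
    sex = np.tile(["M", "F"], n // 2)
    r = np.where(zyg == "MZ", 0.7, 0.45)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    y1 = z1
    y2 = r * z1 + np.sqrt(1 - r**2) * z2
    return pd.DataFrame(
        {
            "pair_id": [f"P{i}" for i in range(n)],
            "zygosity": zyg,
            "sex": sex,
            "site": "UMN",
            "age_months": 120,
            "race": "White",
            "y_1": y1,
            "y_2": y2,
        }
    )
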