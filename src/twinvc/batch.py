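"""Batch orchestration: preprocess -> descriptives -> model battery rows.

Runs the full per-phenotype pipeline across many phenotype columns of one
pair table and emits a fixed-schema, dashboard-style results table. A
phenotype failing at any stage never aborts the batch; its row carries a
machine-readable status code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .biometric import model_battery
from .preprocess import preprocess_table
from .simulate import read_cohort

logger = logging.getLogger("twinvc")

SCHEMA_VERSION = "twinvc.results.v1"

#: fixed, versioned output column order
RESULT_COLUMNS = (
    "phenotype",
    "status",
    "n_mz",
    "n_dz",
    "n_masked",
    "r_mz",
    "r_dz",
    "r_mz_m",
    "r_mz_f",
    "r_dz_m",
    "r_dz_f",
    "levene_zyg_stat",
    "levene_zyg_p",
    "levene_zygsex_stat",
    "levene_zygsex_p",
    "m2ll_sat2",
    "m2ll_ace2",
    "m2ll_sat4",
    "m2ll_ace4_free",
    "m2ll_ace4_equal",
    "p_assumptions",
    "p_sex_het",
    "A",
    "C",
    "E",
    "a2",
    "a2_lo",
    "a2_hi",
    "c2",
    "c2_lo",
    "c2_hi",
    "e2",
    "e2_lo",
    "e2_hi",
    "a2_m",
    "a2_m_lo",
    "a2_m_hi",
    "c2_m",
    "c2_m_lo",
    "c2_m_hi",
    "e2_m",
    "e2_m_lo",
    "e2_m_hi",
    "a2_f",
    "a2_f_lo",
    "a2_f_hi",
    "c2_f",
    "c2_f_lo",
    "c2_f_hi",
    "e2_f",
    "e2_f_lo",
    "e2_f_hi",
    "ade_a2",
    "ade_d2",
    "ade_e2",
    "c_note",
    "converged_all",
)


@dataclass
class RunConfig:
    """One batch run: input, phenotypes, thresholds and output."""

    input_path: str
    phenotypes: list[str]
    output_path: str
    outlier_threshold: float = 4.0
    ci_level: float = 0.95
    seed: int = 0
    sep: str = ","
    log_level: str = "INFO"
    by_sex_ci: bool = True
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.outlier_threshold <= 0:
            raise ValueError("outlier_threshold must be > 0")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run preprocess + battery for every configured phenotype.

    Startup validates that all referenced columns exist and the output is
    writable before any fitting; per-phenotype failures are isolated into
    the row's status field. Identical config + seed reproduces the output
    byte for byte.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    table = read_cohort(config.input_path, sep=config.sep)

    missing_cols = [
        col
        for p in config.phenotypes
        for col in (f"{p}_1", f"{p}_2")
        if col not in table.columns
    ]
    missing_cols += [
        c
        for c in ("zygosity", "sex", "age_months", "race", "site")
        if c not in table.columns
    ]
    if missing_cols:
        raise ValueError(f"input is missing column(s): {missing_cols}")

    out_path = Path(config.output_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    try:
        with open(out_path, "w") as fh:
            fh.write("")
    except OSError as exc:
        raise ValueError(f"output path {out_path} is not writable: {exc}") from exc

    rows = []
    for name in config.phenotypes:
        try:
            prepped, report = preprocess_table(
                table, [name], threshold=config.outlier_threshold
            )
            logger.info(
                "phenotype %s: %d values masked, %d missing on input",
                name,
                report[name]["n_masked"],
                report[name]["n_missing_input"],
            )
            row = model_battery(
                prepped,
                f"{name}_res",
                ci_level=config.ci_level,
                by_sex_ci=config.by_sex_ci,
            )
            row["phenotype"] = name
            row["n_masked"] = report[name]["n_masked"]
        except Exception as exc:  # noqa: BLE001 - isolate per phenotype
            logger.error("phenotype %s failed: %s", name, exc)
            row = {"phenotype": name, "status": f"error:preprocess:{exc}"}
        rows.append(row)

    results = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    write_results(results, out_path, sep=config.sep)
    return results


def write_results(results: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write the results table with the schema tag in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        results.to_csv(fh, sep=sep, index=False)


def read_results(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")
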