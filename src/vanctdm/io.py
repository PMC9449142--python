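"""CSV readers/writers and the JSON run configuration.

All tables are plain comma-separated UTF-8 with "." decimals and
unit-suffixed headers (conc_ugml, baseline_scr_mgdl, ...).  Readers
validate row by row and report every offending line number at once rather
than stopping at the first problem.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cohort import CohortConfig

__all__ = [
    "RunConfig",
    "ReportOptions",
    "ValidationError",
    "read_patients",
    "read_samples",
    "write_table",
]

PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "ibw_kg", "height_cm", "baseline_scr_mgdl",
    "baseline_gfr_mlmin", "dose_mg", "interval_h", "infusion_h",
    "nephrotoxin_cotreat", "aki",
]
SAMPLE_COLUMNS = ["patient_id", "time_h", "conc_ugml"]

SCR_SANITY = (0.1, 15.0)  # mg/dl, unit-confusion guard


class ValidationError(ValueError):
    """Input-table validation failure; carries per-row messages."""

    def __init__(self, messages: list[str]):
        self.messages = messages
        super().__init__("; ".join(messages))


class ReportOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    decimals: int = Field(default=2, ge=0, le=10)
    holm_adjust: bool = False


class RunConfig(BaseModel):
    """End-to-end pipeline configuration; serializes losslessly to JSON."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    cohort: CohortConfig = Field(
        default_factory=lambda: CohortConfig(n_patients=53)
    )
    trough_band: tuple[float, float] = (10.0, 20.0)
    auc_tau_band: tuple[float, float] = (200.0, 300.0)
    auc24_band: tuple[float, float] = (400.0, 600.0)
    report: ReportOptions = Field(default_factory=ReportOptions)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError([f"{what} table missing required columns: {missing}"])


def read_patients(path) -> pd.DataFrame:
    """Read and validate the patient table.

    The AKI column may be absent (estimation-only runs).  Raises
    :class:`ValidationError` listing every bad row by CSV line number.
    """
    df = pd.read_csv(path)
    required = [c for c in PATIENT_COLUMNS if c not in ("aki", "nephrotoxin_cotreat",
                                                        "height_cm", "baseline_gfr_mlmin")]
    _require_columns(df, required, "patients")
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["age"] < 18:
            errors.append(f"line {line}: age {row['age']} below 18")
        if not (SCR_SANITY[0] <= row["baseline_scr_mgdl"] <= SCR_SANITY[1]):
            errors.append(
                f"line {line}: baseline_scr_mgdl {row['baseline_scr_mgdl']} "
                f"outside sanity range {SCR_SANITY}"
            )
        if row["dose_mg"] <= 0:
            errors.append(f"line {line}: non-positive dose_mg")
        if row["interval_h"] <= 0 or not (0 < row["infusion_h"] <= row["interval_h"]):
            errors.append(f"line {line}: invalid interval/infusion durations")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        errors.append(f"duplicate patient_id values: {dups}")
    if errors:
        raise ValidationError(errors)
    return df


def read_samples(path, patients: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate the timed-sample table.

    Concentrations must be non-negative and times must fall within the
    patient's dosing interval when the patient table is supplied.  A
    sample count other than four per patient is a warning, not an error.
    """
    df = pd.read_csv(path)
    _require_columns(df, SAMPLE_COLUMNS, "samples")
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        if row["conc_ugml"] < 0:
            errors.append(
                f"line {line}: negative concentration {row['conc_ugml']}"
            )
        if row["time_h"] < 0:
            errors.append(f"line {line}: negative sample time")
    if patients is not None:
        intervals = patients.set_index("patient_id")["interval_h"]
        for idx, row in df.iterrows():
            tau = intervals.get(row["patient_id"])
            if tau is not None and row["time_h"] > tau:
                errors.append(
                    f"line {idx + 2}: sample time {row['time_h']} beyond "
                    f"interval {tau}"
                )
    if errors:
        raise ValidationError(errors)
    counts = df.groupby("patient_id").size()
    off = counts[counts != 4]
    if len(off):
        warnings.warn(
            f"{len(off)} patient(s) do not have exactly 4 samples "
            f"(ids: {list(off.index[:10])})",
            stacklevel=2,
        )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a report table as plain CSV (full stored precision)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
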