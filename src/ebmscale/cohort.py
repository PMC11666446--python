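"""Cohort container and validated CSV input/output.

A cohort is a pandas DataFrame with one row per subject-test record and
a documented header::

    id, group, age, sex, height_m, mass_kg, speed_mph, grade_frac,
    hr_rest, hr_peak, hrr, rer, vo2peak_ml_min

Extra columns are carried through untouched.  Readers enforce unit
sanity (height in metres, grade as a fraction) with actionable errors —
silent unit mistakes are the most common way these analyses go wrong.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ScalingConstants
from .equations import ebm_allometric, workload_ebm

__all__ = ["Cohort", "read_cohort_csv", "write_cohort_csv", "REQUIRED_COLUMNS"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "id",
    "group",
    "age",
    "sex",
    "height_m",
    "mass_kg",
    "speed_mph",
    "grade_frac",
    "hr_rest",
    "hr_peak",
    "hrr",
    "rer",
    "vo2peak_ml_min",
)

VALID_GROUPS = ("healthy", "cvd", "hf")


def _check_frame(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing required column(s): {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].unique()[:5]
        raise ValueError(f"duplicate subject ids (first few: {list(dupes)})")
    for col in REQUIRED_COLUMNS:
        if df[col].isna().any():
            raise ValueError(f"column {col!r} contains missing values")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValueError(
            f"sex must be the string 'male' or 'female'; offending values: "
            f"{df.loc[bad_sex, 'sex'].unique()[:5].tolist()} (integer sex codes "
            "are rejected to prevent silent miscoding)"
        )
    if (df["height_m"] > 3).any():
        raise ValueError(
            "height_m above 3 m found — heights look like centimetres; divide by 100"
        )
    if (df["height_m"] <= 0).any() or (df["mass_kg"] <= 0).any():
        raise ValueError("height_m and mass_kg must be strictly positive")
    if (df["grade_frac"] > 1).any():
        raise ValueError(
            "grade_frac above 1 found — grades must be fractions (0.11 for 11%); "
            "re-read with grade_percent=True if the file stores percent"
        )
    if (df["grade_frac"] < 0).any():
        raise ValueError("grade_frac must be >= 0")
    for col in ("speed_mph", "hrr"):
        if (df[col] < 0).any():
            raise ValueError(f"{col} must be >= 0")
    if (df["vo2peak_ml_min"] <= 0).any():
        raise ValueError("vo2peak_ml_min must be strictly positive")


@dataclasses.dataclass
class Cohort:
    """Validated table of subject-test records.

    Wraps a DataFrame; analysis functions in this package accept either
    a :class:`Cohort` or a bare DataFrame with the same columns.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _check_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def with_derived(self, constants: ScalingConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
        """Copy of the table with bmi, ebm and wl_mets columns filled in."""
        return add_derived_columns(self.df, constants)


def as_frame(cohort) -> pd.DataFrame:
    """Accept a Cohort or DataFrame and return the underlying frame."""
    return cohort.df if isinstance(cohort, Cohort) else cohort


def add_derived_columns(
    df: pd.DataFrame, constants: ScalingConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    df = df.copy()
    if "bmi" not in df.columns:
        df["bmi"] = df["mass_kg"] / df["height_m"] ** 2
    if "ebm" not in df.columns:
        df["ebm"] = ebm_allometric(
            df["mass_kg"].to_numpy(),
            df["height_m"].to_numpy(),
            df["sex"].to_numpy(),
            df["age"].to_numpy(),
            constants,
        )
    if "wl_mets" not in df.columns:
        df["wl_mets"] = workload_ebm(
            df["speed_mph"].to_numpy(),
            df["grade_frac"].to_numpy(),
            df["hrr"].to_numpy(),
            constants,
        )
    return df


def read_cohort_csv(path: str | Path, grade_percent: bool = False) -> Cohort:
    """Read a cohort CSV, normalising sex strings and deriving HRR.

    ``grade_percent=True`` declares that grade_frac is stored in percent
    and divides by 100 on read.  HRR is derived as hr_peak − hr_rest
    when the hrr column is absent or has gaps; rows where it cannot be
    derived are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "sex" in df.columns:
        df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    if grade_percent and "grade_frac" in df.columns:
        df["grade_frac"] = df["grade_frac"] / 100.0
    if "hrr" not in df.columns:
        df["hrr"] = np.nan
    derivable = df["hrr"].isna() & df["hr_peak"].notna() & df["hr_rest"].notna()
    df.loc[derivable, "hrr"] = df.loc[derivable, "hr_peak"] - df.loc[derivable, "hr_rest"]
    dropped = int(df["hrr"].isna().sum())
    if dropped:
        logger.warning(
            "%d row(s) dropped: HRR missing and not derivable from hr_peak/hr_rest",
            dropped,
        )
        df = df[df["hrr"].notna()]
    return Cohort(df)


def write_cohort_csv(cohort: Cohort | pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort to CSV (RFC-4180 via pandas), preserving extra columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    as_frame(cohort).to_csv(path, index=False)
    return path
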