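"""Cohort data schema, loading and design-matrix construction.

The whole pipeline reads and writes one long-format CSV with one row per
completed questionnaire:

====================  =========================================================
column                meaning
====================  =========================================================
patient_id            grouping key for repeated measures
time                  years since transplantation (>= 0)
hsuv                  health-state utility value in [u_min, u_max]; may be
                      absent when ``eq5d_profile`` is given instead
eq5d_profile          optional 5-digit EQ-5D-3L profile string (e.g. "21131")
age                   recipient age at transplantation (years)
sex                   male indicator (1 = man, 0 = woman)
bmi_lt18, bmi_gt30    BMI category indicators (reference: 18-30 kg/m2)
diabetes              history-of-diabetes indicator
cardiovascular        history-of-cardiovascular-disease indicator
neoplasia             history-of-neoplasia indicator
hypertension          history-of-hypertension indicator
dialysis_years        years on dialysis before transplantation
first_transplant      first (vs second) graft indicator
relapsing_nephropathy relapsing initial nephropathy indicator
donor_age             donor age (years)
====================  =========================================================

Baseline covariates are constant within a patient.  Rows with missing
values on the covariates used by a model are dropped as complete-case
exclusions, and the exclusion is counted per patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .transforms import time_basis
from .valueset import ValueSet, score_profile

__all__ = [
    "ALL_COVARIATES",
    "FINAL_MODEL_COVARIATES",
    "CohortData",
    "load_cohort",
    "prepare_cohort",
    "build_design",
]

#: Baseline characteristics considered candidate predictors.
ALL_COVARIATES = (
    "age",
    "sex",
    "bmi_gt30",
    "bmi_lt18",
    "diabetes",
    "cardiovascular",
    "neoplasia",
    "hypertension",
    "dialysis_years",
    "first_transplant",
    "relapsing_nephropathy",
    "donor_age",
)

#: Covariates retained by forward selection in the reference analysis.
FINAL_MODEL_COVARIATES = (
    "age",
    "sex",
    "bmi_gt30",
    "diabetes",
    "cardiovascular",
    "dialysis_years",
)

REQUIRED_COLUMNS = ("patient_id", "time")


@dataclass
class CohortData:
    """A validated cohort in long format, sorted by patient then time.

    ``df`` carries one row per questionnaire; ``n_excluded_patients`` and
    ``n_excluded_obs`` count complete-case exclusions applied by
    :func:`prepare_cohort`.
    """

    df: pd.DataFrame
    n_excluded_patients: int = 0
    n_excluded_obs: int = 0

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def patient_index(self) -> np.ndarray:
        """Dense patient codes aligned with rows (contiguous per patient)."""
        return self.df["patient_id"].factorize()[0]


def load_cohort(path: str | Path, value_set: ValueSet | None = None) -> pd.DataFrame:
    """Read a cohort CSV, scoring EQ-5D profiles into ``hsuv`` if needed."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort file {path} lacks required column(s): {missing}")
    if "hsuv" not in df.columns:
        if "eq5d_profile" not in df.columns:
            raise DataError(f"cohort file {path} has neither 'hsuv' nor 'eq5d_profile'")
        if value_set is None:
            raise DataError("a value set is required to score 'eq5d_profile' into 'hsuv'")
        df["hsuv"] = [
            score_profile(str(p).zfill(5), value_set) for p in df["eq5d_profile"]
        ]
    return df


def prepare_cohort(
    df: pd.DataFrame,
    covariates: Sequence[str],
    u_min: float = -0.53,
    u_max: float = 1.00,
    first_transplant_only: bool = False,
    check_range: bool = True,
) -> CohortData:
    """Validate, complete-case filter and sort a cohort for fitting.

    Rows missing ``hsuv``, ``time`` or any requested covariate are
    dropped; exclusions are counted at both observation and patient
    level (a patient is "excluded" when all of their rows are dropped).
    ``first_transplant_only`` restricts to first grafts (sensitivity
    analysis).
    """
    for col in ("hsuv",) + tuple(REQUIRED_COLUMNS):
        if col not in df.columns:
            raise DataError(f"cohort lacks required column {col!r}")
    for cov in covariates:
        if cov not in df.columns:
            raise DataError(f"cohort lacks covariate column {cov!r}")
    df = df.copy()
    if first_transplant_only:
        if "first_transplant" not in df.columns:
            raise DataError("first_transplant column required for the subset refit")
        df = df[df["first_transplant"] == 1]

    needed = ["hsuv", "time", *covariates]
    keep = df[needed].notna().all(axis=1)
    before_patients = df["patient_id"].nunique()
    out = df[keep].copy()
    n_excluded_obs = int((~keep).sum())
    n_excluded_patients = before_patients - out["patient_id"].nunique()

    if len(out) == 0:
        return CohortData(out, n_excluded_patients, n_excluded_obs)
    u = out["hsuv"].to_numpy(float)
    if check_range and (np.any(u < u_min - 1e-9) or np.any(u > u_max + 1e-9)):
        raise DataError(
            f"hsuv outside [{u_min}, {u_max}]: observed range [{u.min()}, {u.max()}]"
        )
    t = out["time"].to_numpy(float)
    if np.any(t < 0):
        raise DataError("negative time since transplantation")
    out = out.sort_values(["patient_id", "time"], kind="stable").reset_index(drop=True)
    return CohortData(out, n_excluded_patients, n_excluded_obs)


def build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    knot: float = 1.0,
    centering: dict[str, float] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix: intercept, covariates, two time slopes.

    Continuous covariates are used uncentred unless ``centering`` maps a
    covariate name to the value to subtract (affects only the intercept's
    interpretation).
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        if cov not in df.columns:
            raise DataError(f"missing covariate column {cov!r}")
        x = df[cov].to_numpy(float)
        if centering and cov in centering:
            x = x - centering[cov]
        cols.append(x)
        names.append(cov)
    t_pre, t_post = time_basis(df["time"].to_numpy(float), knot=knot)
    cols += [t_pre, t_post]
    names += ["t_pre", "t_post"]
    return np.column_stack(cols), names
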