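"""Quality filtering and confound removal for tract-profile tables.

A tract-profile table is a pandas DataFrame with one row per participant and
columns ``participant_id``, ``cohort_id``, ``age``, ``gender``, optionally
``qc_displacement`` (mm), plus one column per named tract holding FA (or GFA)
values.  Residualization regresses age (linear and squared) and gender out of
every tract and standardizes the residuals to zero mean / unit variance
within each cohort, so the similarity network downstream captures age- and
gender-invariant microstructural differences and is comparable across
scanning protocols.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("participant_id", "cohort_id", "age", "gender", "qc_displacement")


def tract_columns(table: pd.DataFrame) -> list[str]:
    """Columns holding tract values (everything that is not metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


@dataclass
class ResidualizedProfiles:
    """Confound-residualized, standardized profiles with the fitted
    coefficients retained for audit.

    ``data`` has the same layout as the input table; ``coefficients`` is
    indexed by (cohort_id, tract) with columns intercept/age/age2/gender
    (NaN where a column was dropped from the design).
    """

    data: pd.DataFrame
    coefficients: pd.DataFrame

    def values(self) -> np.ndarray:
        return self.data[tract_columns(self.data)].to_numpy(dtype=float)


def qc_filter(table: pd.DataFrame, max_displacement_mm: float = 3.0) -> pd.DataFrame:
    """Drop participants whose between-volume displacement reaches the limit.

    The comparison is strict: rows survive only with displacement strictly
    below ``max_displacement_mm``. Rows lacking the QC column pass with a
    warning.  An empty result is an error.
    """
    if max_displacement_mm <= 0:
        raise ValueError("max_displacement_mm must be positive")
    if "qc_displacement" not in table.columns:
        warnings.warn("no qc_displacement column; all rows pass QC", stacklevel=2)
        return table.copy()
    disp = table["qc_displacement"]
    keep = disp.isna() | (disp < max_displacement_mm)
    if disp.isna().any():
        warnings.warn(
            f"{int(disp.isna().sum())} rows lack a displacement value and pass QC",
            stacklevel=2,
        )
    removed = table.loc[~keep, "participant_id"].tolist()
    if removed:
        logger.info("QC removed %d participants: %s", len(removed), removed)
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("QC filter removed every participant")
    return out


def _residualize_cohort(sub: pd.DataFrame, tracts: list[str]) -> tuple[np.ndarray, pd.DataFrame]:
    age = sub["age"].to_numpy(dtype=float)
    if len(sub) < 5:
        raise ValueError("need at least 5 participants per cohort to residualize")
    if np.var(age) == 0:
        raise ValueError("age has zero variance; cannot fit confound model")
    age_c = age - age.mean()
    gender = sub["gender"].to_numpy(dtype=float)
    cols = ["intercept", "age", "age2", "gender"]
    design = [np.ones_like(age), age_c, age_c ** 2, gender]
    if np.all(gender == gender[0]):
        warnings.warn("single gender present; dropping gender from design", stacklevel=3)
        design = design[:3]
        cols = cols[:3]
    X = np.column_stack(design)

    Y = sub[tracts].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=0)
    zero_var = sd <= 1e-10 * np.maximum(1.0, np.abs(Y).max(axis=0))
    if zero_var.any():
        bad = [t for t, z in zip(tracts, zero_var) if z]
        raise ValueError(f"constant tract values (zero residual variance): {bad}")
    resid = (resid - resid.mean(axis=0)) / sd

    coef = pd.DataFrame(beta.T, index=tracts, columns=cols).reindex(
        columns=["intercept", "age", "age2", "gender"]
    )
    return resid, coef


def residualize(table: pd.DataFrame) -> ResidualizedProfiles:
    """OLS-residualize each tract on intercept + age + age^2 + gender, then
    z-score within cohort.

    Age is centered before squaring (same column space, better conditioning).
    Fitting is always within each ``cohort_id`` separately, never pooled.
    """
    tracts = tract_columns(table)
    if not tracts:
        raise ValueError("no tract columns found")
    out = table.copy()
    cohorts = table["cohort_id"].unique() if "cohort_id" in table.columns else [None]
    coefs = []
    for coh in cohorts:
        mask = slice(None) if coh is None else (table["cohort_id"] == coh).to_numpy()
        sub = table.loc[mask] if coh is not None else table
        resid, coef = _residualize_cohort(sub, tracts)
        out.loc[sub.index, tracts] = resid
        coef.insert(0, "cohort_id", coh if coh is not None else "all")
        coefs.append(coef.rename_axis("tract").reset_index())
    coefficients = pd.concat(coefs, ignore_index=True).set_index(["cohort_id", "tract"])
    return ResidualizedProfiles(data=out, coefficients=coefficients)
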