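"""Structural-part design matrices.

One shared expansion from *logical* covariate names (``"dqi"``, ``"age"``,
``"education"``, ...) to numeric design columns, used identically by the
synthetic-data generator and the model fitter so simulated truth and fitted
coefficients always refer to the same columns.  Categorical covariates are
reference-coded; age is centred at 50 years for sampler geometry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["AGE_CENTER", "LOGICAL_COVARIATES", "design_matrix", "expanded_names"]

AGE_CENTER = 50.0

# logical name -> list of (design column name, builder)
_EXPANSIONS: dict[str, list[tuple[str, callable]]] = {
    "dqi": [("dqi", lambda df: df["dqi"].to_numpy(dtype=float))],
    "age": [("age_c", lambda df: df["age"].to_numpy(dtype=float) - AGE_CENTER)],
    "sex": [("sex_male", lambda df: (df["sex"] == "male").to_numpy(dtype=float))],
    "education": [
        ("education_2", lambda df: (df["education"] == 2).to_numpy(dtype=float)),
        ("education_3", lambda df: (df["education"] == 3).to_numpy(dtype=float)),
    ],
    "residence": [
        ("residence_urban", lambda df: (df["residence"] == "urban").to_numpy(dtype=float))
    ],
    "marital": [
        ("marital_married", lambda df: (df["marital"] == "married").to_numpy(dtype=float))
    ],
    "smoking": [
        ("smoking_ever", lambda df: (df["smoking"] == "ever").to_numpy(dtype=float))
    ],
    "physical_activity": [
        ("pa_tertile_2", lambda df: (df["pa_tertile"] == 2).to_numpy(dtype=float)),
        ("pa_tertile_3", lambda df: (df["pa_tertile"] == 3).to_numpy(dtype=float)),
    ],
    "coping_adaptive": [
        ("coping_adaptive_2", lambda df: (df["coping_adaptive_tertile"] == 2).to_numpy(dtype=float)),
        ("coping_adaptive_3", lambda df: (df["coping_adaptive_tertile"] == 3).to_numpy(dtype=float)),
    ],
    "coping_maladaptive": [
        ("coping_maladaptive_2", lambda df: (df["coping_maladaptive_tertile"] == 2).to_numpy(dtype=float)),
        ("coping_maladaptive_3", lambda df: (df["coping_maladaptive_tertile"] == 3).to_numpy(dtype=float)),
    ],
    "med_dyslipidemia": [
        ("med_dyslipidemia", lambda df: df["med_dyslipidemia"].to_numpy(dtype=float))
    ],
    "med_hypertension": [
        ("med_hypertension", lambda df: df["med_hypertension"].to_numpy(dtype=float))
    ],
    "med_diabetes": [
        ("med_diabetes", lambda df: df["med_diabetes"].to_numpy(dtype=float))
    ],
    "family_history": [
        ("family_history", lambda df: df["family_history"].to_numpy(dtype=float))
    ],
}

#: Logical covariate names the expansion understands.
LOGICAL_COVARIATES: tuple[str, ...] = tuple(_EXPANSIONS)

# raw cohort columns each logical covariate needs
_REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "dqi": ("dqi",),
    "age": ("age",),
    "sex": ("sex",),
    "education": ("education",),
    "residence": ("residence",),
    "marital": ("marital",),
    "smoking": ("smoking",),
    "physical_activity": ("pa_tertile",),
    "coping_adaptive": ("coping_adaptive_tertile",),
    "coping_maladaptive": ("coping_maladaptive_tertile",),
    "med_dyslipidemia": ("med_dyslipidemia",),
    "med_hypertension": ("med_hypertension",),
    "med_diabetes": ("med_diabetes",),
    "family_history": ("family_history",),
}


def expanded_names(covariates: list[str] | tuple[str, ...]) -> list[str]:
    """Design column names produced by a list of logical covariates."""
    names: list[str] = []
    for cov in covariates:
        if cov not in _EXPANSIONS:
            raise ValueError(f"unknown covariate {cov!r}; known: {LOGICAL_COVARIATES}")
        names.extend(name for name, _ in _EXPANSIONS[cov])
    return names


def design_matrix(
    df: pd.DataFrame, covariates: list[str] | tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Build the structural design matrix for the requested covariates.

    Returns ``(X, column_names)`` with ``X`` of shape (rows, columns).  There
    is no intercept column: the item thresholds absorb the latent location.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in _EXPANSIONS:
            raise ValueError(f"unknown covariate {cov!r}; known: {LOGICAL_COVARIATES}")
        missing = [c for c in _REQUIRED_COLUMNS[cov] if c not in df.columns]
        if missing:
            raise ValueError(f"covariate {cov!r} needs column(s) {missing} absent from table")
        for name, builder in _EXPANSIONS[cov]:
            cols.append(np.asarray(builder(df), dtype=float))
            names.append(name)
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names
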