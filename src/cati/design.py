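"""Shared design-matrix helpers for the regression stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .weighting import DataError

COMPONENT_PREFIX = "comp_"


def component_frame(cohort: pd.DataFrame, names=None) -> pd.DataFrame:
    """Extract the 0/1 component columns, stripped of their prefix."""
    cols = {c[len(COMPONENT_PREFIX):]: c for c in cohort.columns if c.startswith(COMPONENT_PREFIX)}
    if names is None:
        names = list(cols)
    missing = [n for n in names if n not in cols]
    if missing:
        raise DataError(f"components not present in cohort: {missing}")
    out = cohort[[cols[n] for n in names]].copy()
    out.columns = list(names)
    return out


def demographic_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographic controls used throughout: continuous age, a female
    indicator, and race/ethnicity dummies with 'white' as reference."""
    out = pd.DataFrame(index=cohort.index)
    out["age"] = cohort["age"].astype(float)
    out["female"] = (cohort["sex"] == "female").astype(float)
    for level in ("black", "latinx", "other"):
        out[f"race_{level}"] = (cohort["race_ethnicity"] == level).astype(float)
    return out


def earnings_controls_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extra controls for the peak-earnings model: observed years aged
    20-29, enrollment at the peak year, and household position (head as
    reference)."""
    out = pd.DataFrame(index=cohort.index)
    out["years_observed_20_29"] = cohort["years_observed_20_29"].astype(float)
    out["enrolled_at_peak"] = cohort["enrolled_at_peak"].astype(float)
    for level in ("spouse", "other"):
        out[f"household_{level}"] = (cohort["household_position"] == level).astype(float)
    return out


def add_constant(X: pd.DataFrame) -> pd.DataFrame:
    out = X.copy()
    out.insert(0, "const", 1.0)
    return out


def as_matrix(*frames) -> np.ndarray:
    return np.column_stack([np.asarray(f, dtype=float) for f in frames])
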