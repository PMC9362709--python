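"""Published reference values for the CATI 1.0 derivation (golden fixture).

The original index was derived on restricted panel microdata that cannot be
redistributed, but its published derivation prints every input the weight
formula needs: the first-principal-component loadings of the five
subjective scales (with all five eigenvalues) and the final pooled
regression coefficient of each surviving component on each scale, with
removed cells marked by the stage that removed them.  Re-applying the
double-weighting rule to those printed inputs must reproduce the published
normalized weights to within their three-decimal rounding; that check is
:func:`cati.pipeline.golden_check`.

Values are stored to the printed three-decimal precision.  Version: CATI 1.0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .weighting import SCALES, LoadingVector

#: First-PC factor loadings of the five scales (unit-norm eigenvector).
REFERENCE_LOADINGS = {"fl": 0.475, "pd": -0.502, "wr": -0.475, "sa": -0.392, "ls": 0.378}

#: All five eigenvalues of the scale correlation matrix (descending).
REFERENCE_EIGENVALUES = (2.62, 0.92, 0.55, 0.48, 0.42)

#: Final pooled coefficients per (component, scale); cells removed by the
#: adaptive-LASSO stage or by post-LASSO backward elimination are None and
#: enter the weight formula as 0.  The removal stage is kept for display.
_REF_ROWS = [
    # name,                 fl,     pd,     wr,     sa,     ls
    ("food_secure",          0.168, -0.166, -0.228, -0.177,  0.171),
    ("attended_preschool",   None,  -0.102,  None,   None,   None),
    ("graduated_hs_on_time", 0.274, -0.224, -0.357, -0.171,  0.273),
    ("math_proficient",      None,   None,  -0.121, -0.118,  None),
    ("reading_proficient",   0.163, -0.067,  None,   None,   None),
    ("non_low_birthweight",  0.123,  None,  -0.096,  None,   None),
    ("non_obese",            None,   None,  -0.084,  None,   None),
    ("not_fair_poor_health", None,   None,   None,  -0.136,  None),
    ("didnt_smoke",          0.236, -0.224, -0.267,  None,   0.104),
    ("didnt_try_marijuana",  None,  -0.130,  None,   None,   0.192),
    ("never_pregnant",       None,   None,   None,   None,   None),
    ("never_arrested",       None,   None,   None,   None,   0.141),
]

_REF_STATUS = {
    "attended_preschool":   {"fl": "POST", "wr": "POST", "sa": "LASSO", "ls": "LASSO"},
    "math_proficient":      {"fl": "POST", "pd": "LASSO", "ls": "LASSO"},
    "reading_proficient":   {"wr": "POST", "sa": "POST", "ls": "LASSO"},
    "non_low_birthweight":  {"pd": "LASSO", "sa": "LASSO", "ls": "LASSO"},
    "non_obese":            {"fl": "LASSO", "pd": "POST", "sa": "LASSO", "ls": "LASSO"},
    "not_fair_poor_health": {"fl": "LASSO", "pd": "POST", "wr": "LASSO", "ls": "LASSO"},
    "didnt_smoke":          {"sa": "POST"},
    "didnt_try_marijuana":  {"fl": "POST", "wr": "POST", "sa": "POST"},
    "never_pregnant":       {"fl": "LASSO", "pd": "LASSO", "wr": "LASSO", "sa": "POST", "ls": "LASSO"},
    "never_arrested":       {"fl": "POST", "pd": "LASSO", "wr": "LASSO", "sa": "POST"},
}

#: Published normalized index weights (components with zero weight omitted,
#: as in the published table).
REFERENCE_WEIGHTS = {
    "food_secure": 0.199,
    "attended_preschool": 0.025,
    "graduated_hs_on_time": 0.285,
    "math_proficient": 0.052,
    "reading_proficient": 0.054,
    "non_low_birthweight": 0.052,
    "non_obese": 0.020,
    "not_fair_poor_health": 0.027,
    "didnt_smoke": 0.192,
    "didnt_try_marijuana": 0.069,
    "never_arrested": 0.027,
}

#: Share of the total weight carried by the three largest components
#: (on-time graduation, food security, not smoking), as published.
REFERENCE_TOP3_SHARE = 0.676


def reference_loadings() -> LoadingVector:
    return LoadingVector(
        loadings=pd.Series(REFERENCE_LOADINGS, index=list(SCALES)),
        eigenvalues=np.array(REFERENCE_EIGENVALUES),
    )


def reference_coefficients(drop_all_zero: bool = False) -> pd.DataFrame:
    """(scales x components) coefficient matrix with removed cells as 0."""
    data = {name: [0.0 if v is None else v for v in vals] for name, *vals in _REF_ROWS}
    beta = pd.DataFrame(data, index=list(SCALES))
    if drop_all_zero:
        beta = beta.loc[:, (beta != 0).any(axis=0)]
    return beta


def reference_status() -> pd.DataFrame:
    """Removal-stage table ('kept' / 'LASSO' / 'POST') for display parity."""
    out = pd.DataFrame("kept", index=[r[0] for r in _REF_ROWS], columns=list(SCALES))
    for comp, cells in _REF_STATUS.items():
        for scale, status in cells.items():
            out.loc[comp, scale] = status
    return out
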