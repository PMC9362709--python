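"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from cati import (
    PipelineConfig,
    apply_missingness,
    generate_cohort,
    impute_chained,
    psid_like_config,
)


@pytest.fixture(scope="session")
def preset_config():
    return psid_like_config(n_children=2000, seed=20260923)


@pytest.fixture(scope="session")
def complete_cohort(preset_config):
    """Fully observed panel-like cohort, n=2000."""
    return generate_cohort(preset_config)


@pytest.fixture(scope="session")
def missing_cohort(preset_config, complete_cohort):
    """Same cohort with ~40% of rows carrying at least one missing cell."""
    return apply_missingness(complete_cohort, preset_config)


@pytest.fixture(scope="session")
def small_imputations(missing_cohort):
    """m=4 completed copies of the missing cohort (kept small for speed)."""
    return impute_chained(missing_cohort, m=4, seed=7, n_iter=5)


def make_validity_frame(n: int, seed: int, score_effect: float = 0.0,
                        p_outcome: float = 0.3) -> pd.DataFrame:
    """Minimal frame with the demographic/control schema plus a standardized
    score column, for validity-model unit tests."""
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    score = (score - score.mean()) / score.std(ddof=1)
    from scipy.special import expit, logit

    p = expit(logit(p_outcome) + score_effect * score)
    df = pd.DataFrame(
        {
            "age": rng.uniform(19, 27, n),
            "sex": rng.choice(["male", "female"], n),
            "race_ethnicity": rng.choice(["white", "black", "latinx", "other"], n),
            "attrition_weight": np.exp(rng.normal(0, 0.2, n)),
            "score": score,
            "ever_fair_poor_health": (rng.random(n) < p).astype(float),
            "years_observed_20_29": rng.integers(4, 11, n).astype(float),
            "enrolled_at_peak": (rng.random(n) < 0.25).astype(float),
            "household_position": rng.choice(["head", "spouse", "other"], n),
        }
    )
    df["attrition_weight"] /= df["attrition_weight"].mean()
    return df
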