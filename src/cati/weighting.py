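"""PCA double weighting: aggregate per-scale regression coefficients into a
single normalized component-weight vector, and score individuals.

The hedonic weighting scheme runs one regression of each (standardized)
subjective well-being scale on the surviving 0/1 components, then combines
the five coefficient vectors using the first-principal-component loadings of
the scales.  For component z with coefficient ``beta[j, z]`` on scale j and
loading ``l[j]``::

    W_z       = mean_j |l[j] * beta[j, z]|
    CompWght_z = W_z / sum_z W_z

The absolute value is essential: deficit-pointing scales (distress, worry,
social anxiety) carry negative loadings and negative coefficients for
positively framed components, and without it their products would cancel the
flourishing/life-satisfaction terms instead of reinforcing them.  The mean
is always taken over *all* benchmark scales — a component removed from a
scale's equation contributes a zero coefficient, not a smaller divisor.

An individual's index score is the dot product of their 0/1 component vector
with the normalized weights, so it lives in [0, 1] and flipping component z
from 0 to 1 raises the score by exactly ``CompWght_z``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical order of the five subjective scales: flourishing, psychological
#: distress, economic worry, social anxiety, life satisfaction.
SCALES = ("fl", "pd", "wr", "sa", "ls")

SCALE_LABELS = {
    "fl": "Flourishing",
    "pd": "Psychological Distress",
    "wr": "Economic Worry",
    "sa": "Social Anxiety",
    "ls": "Life Satisfaction",
}


class DataError(ValueError):
    """Raised when input data violate a pipeline precondition."""


@dataclass
class LoadingVector:
    """First-principal-component loadings of the benchmark scales.

    ``loadings`` has unit Euclidean norm and is oriented so the flourishing
    entry (or, generally, the first well-being-positive scale present) is
    positive; ``eigenvalues`` are all eigenvalues in descending order and
    sum to the number of scales for a correlation-matrix PCA.
    """

    loadings: pd.Series
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)


@dataclass
class WeightVector:
    """Raw (pre-normalization) and normalized component weights."""

    raw: pd.Series
    normalized: pd.Series

    @property
    def names(self) -> list:
        return list(self.normalized.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"raw_weight": self.raw, "weight": self.normalized})


@dataclass
class IndexScores:
    """Per-respondent index scores: raw (in [0, 1]) and standardized."""

    values: pd.Series
    standardized: pd.Series


def standardize(x, ddof: int = 1) -> np.ndarray:
    """Z-score an array; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DataError("cannot standardize a constant (or empty) column")
    return (x - x.mean()) / sd


def wave_columns(df: pd.DataFrame, scale: str) -> list:
    pat = re.compile(rf"^{scale}_w\d+$")
    cols = sorted(c for c in df.columns if pat.match(c))
    if not cols and scale in df.columns:
        cols = [scale]
    return cols


def preprocess_scales(cohort: pd.DataFrame, scales=SCALES) -> pd.DataFrame:
    """Average each subjective scale within person across waves, then z-score.

    Requires at least one observed wave per scale per respondent (always
    true post-imputation).  Returns an n x len(scales) standardized matrix.
    """
    out = {}
    for scale in scales:
        cols = wave_columns(cohort, scale)
        if not cols:
            raise DataError(f"no wave columns found for scale {scale!r}")
        mean = cohort[cols].mean(axis=1)  # skips NaN waves
        if mean.isna().any():
            bad = int(mean.isna().sum())
            raise DataError(f"scale {scale!r}: {bad} respondents with no observed wave")
        try:
            out[scale] = standardize(mean.to_numpy())
        except DataError as exc:
            raise DataError(f"scale {scale!r} has zero variance") from exc
    return pd.DataFrame(out, index=cohort.index)


def _first_pc_from_corr(corr: np.ndarray, names, orient: str = "fl") -> LoadingVector:
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[-1] < 1e-10:
        raise DataError("scale correlation matrix is rank-deficient")
    first = eigvecs[:, 0]
    names = list(names)
    anchor = names.index(orient) if orient in names else 0
    if first[anchor] < 0:
        first = -first
    if len(eigvals) > 1 and eigvals[1] > 1.0:
        warnings.warn(
            f"second eigenvalue {eigvals[1]:.3f} exceeds 1; the Kaiser criterion "
            "would admit more than one principal component",
            stacklevel=3,
        )
    return LoadingVector(loadings=pd.Series(first, index=names), eigenvalues=eigvals)


def pca_first_component(scales: pd.DataFrame) -> LoadingVector:
    """Correlation-matrix PCA of the standardized scales.

    Returns all eigenvalues plus the first eigenvector, sign-fixed so the
    flourishing loading is positive.  Warns if the second eigenvalue also
    exceeds 1 (the single-component design would then be questionable).
    """
    if len(scales) < len(scales.columns) + 1:
        raise DataError("need more observations than scales for PCA")
    corr = np.corrcoef(scales.to_numpy(), rowvar=False)
    return _first_pc_from_corr(corr, scales.columns)


def pca_from_imputations(scale_matrices) -> LoadingVector:
    """PCA under multiple imputation: average the per-imputation correlation
    matrices, then eigendecompose once (symmetric in imputations and
    deterministic)."""
    mats = [np.corrcoef(s.to_numpy(), rowvar=False) for s in scale_matrices]
    if not mats:
        raise DataError("no imputations supplied")
    names = list(scale_matrices[0].columns)
    return _first_pc_from_corr(np.mean(mats, axis=0), names)


def compute_weights(loadings: LoadingVector, coefficients) -> WeightVector:
    """Double-weighting aggregation (absolute-value form).

    ``coefficients`` is a (scales x components) DataFrame — or any object
    with a ``.beta`` DataFrame attribute — with zeros for components removed
    from a scale's equation.  Demographic coefficients must not be included.
    """
    beta = coefficients.beta if hasattr(coefficients, "beta") else coefficients
    beta = beta.reindex(index=loadings.loadings.index)
    if beta.isna().any().any():
        raise DataError("coefficient matrix does not cover all benchmark scales")
    lam = loadings.loadings.to_numpy()[:, None]
    raw = pd.Series(np.abs(lam * beta.to_numpy()).mean(axis=0), index=beta.columns)
    total = raw.sum()
    if total <= 0:
        raise DataError("all raw weights are zero: no informative components")
    return WeightVector(raw=raw, normalized=raw / total)


def single_benchmark_loadings(name: str) -> LoadingVector:
    """Degenerate loading vector for weighting against a single benchmark
    outcome, under which the weights reduce to normalized |beta|."""
    return LoadingVector(loadings=pd.Series([1.0], index=[name]), eigenvalues=np.array([1.0]))


def score_index(components: pd.DataFrame, weights: WeightVector) -> IndexScores:
    """Score respondents: dot product of 0/1 component values with the
    normalized weights, plus the sample-standardized variant."""
    names = weights.names
    missing = [n for n in names if n not in components.columns]
    if missing:
        raise DataError(f"component columns absent from data: {missing}")
    mat = components[names]
    if mat.isna().any().any():
        raise DataError("component matrix contains missing values; impute first")
    values = pd.Series(mat.to_numpy(float) @ weights.normalized.to_numpy(), index=components.index)
    return IndexScores(values=values, standardized=pd.Series(standardize(values), index=values.index))
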