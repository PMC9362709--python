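"""Predictive validity of an index against young-adult outcomes.

For the binary outcomes (ever fair/poor health, ever depressed) an
attrition-weighted logistic regression of the outcome on the standardized
index score plus demographics yields an average marginal effect (AME): the
sample-weighted mean of ``p(score + 1) - p(score)``, i.e. the
percentage-point change associated with a one-standard-deviation increase
in the index.  Its variance comes from the delta method.  For peak
earnings a weighted Poisson regression with a robust (sandwich) covariance
yields the percent change per SD, ``100 * (exp(beta) - 1)``.  Partial R^2
is Efron's squared-correlation pseudo-R^2 of the full model minus that of
the controls-only model — a definition that coincides with ordinary R^2 in
the linear case, so the full-minus-base arithmetic is well defined across
outcome types.  All quantities are pooled over imputations with the
standard multiple-imputation rules.

Two indices fitted on the same sample are compared by stacking their
estimating equations: the joint sandwich covariance of the two coefficient
vectors (with a cross block built from per-observation score
contributions) propagates through the AME difference, accounting for the
shared sample.  A seeded paired bootstrap is available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .design import add_constant, demographic_design, earnings_controls_design
from .imputation import pool_estimates
from .weighting import DataError, IndexScores, standardize


@dataclass
class MarginalEffect:
    """A pooled 1-SD marginal effect with its explained-variance increment."""

    outcome: str
    index_name: str
    estimate: float
    ci95: tuple
    se: float
    p_value: float
    partial_r2: float
    r2_full: float
    r2_base: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "index": self.index_name,
            "estimate": self.estimate,
            "ci95": list(self.ci95),
            "se": self.se,
            "p_value": self.p_value,
            "partial_r2": self.partial_r2,
            "r2_full": self.r2_full,
            "r2_base": self.r2_base,
            **self.extra,
        }


@dataclass
class ComparisonResult:
    pair: tuple
    difference: float
    se: float
    p_value: float
    method: str


# ---------------------------------------------------------------------------
# weighted GLM internals (logit / poisson) with analytic gradients
# ---------------------------------------------------------------------------

def _glm_irls(X, y, w, family: str):
    fam = sm.families.Binomial() if family == "logit" else sm.families.Poisson()
    return sm.GLM(y, X, family=fam, var_weights=w).fit().params


def _glm_parts(X, y, w, beta, family: str):
    """Information matrix, per-observation score contributions, and mean."""
    eta = X @ beta
    if family == "logit":
        mu = expit(eta)
        var = np.clip(mu * (1 - mu), 1e-10, None)
    else:
        mu = np.exp(np.clip(eta, -30, 30))
        var = np.clip(mu, 1e-10, None)
    H = X.T @ (X * (w * var)[:, None])
    scores = X * (w * (y - mu))[:, None]
    return H, scores, mu


@dataclass
class _Fit:
    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    beta: np.ndarray
    H: np.ndarray
    scores: np.ndarray
    mu: np.ndarray
    family: str
    score_col: int
    columns: list

    @property
    def cov_robust(self) -> np.ndarray:
        Hinv = np.linalg.inv(self.H)
        meat = self.scores.T @ self.scores
        return Hinv @ meat @ Hinv

    @property
    def cov_model(self) -> np.ndarray:
        return np.linalg.inv(self.H)


def _fit_glm(X: pd.DataFrame, y, w, family: str, score_col: str = "score") -> _Fit:
    Xm = X.to_numpy(float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    beta = _glm_irls(Xm, y, w, family)
    H, scores, mu = _glm_parts(Xm, y, w, beta, family)
    return _Fit(Xm, y, w, beta, H, scores, mu, family,
                list(X.columns).index(score_col) if score_col in X.columns else -1,
                list(X.columns))


def _ame_logit(fit: _Fit):
    """Weighted AME of a +1 shift in the score column, with delta-method
    gradient with respect to the full coefficient vector."""
    j = fit.score_col
    eta0 = fit.X @ fit.beta
    eta1 = eta0 + fit.beta[j]
    p0, p1 = expit(eta0), expit(eta1)
    wsum = fit.w.sum()
    ame = float(np.sum(fit.w * (p1 - p0)) / wsum)
    X1 = fit.X.copy()
    X1[:, j] += 1.0
    g = (X1 * (fit.w * p1 * (1 - p1))[:, None] - fit.X * (fit.w * p0 * (1 - p0))[:, None]).sum(
        axis=0
    ) / wsum
    return ame, g


def _efron_r2(y, mu, w) -> float:
    ybar = np.average(y, weights=w)
    denom = np.sum(w * (y - ybar) ** 2)
    return float(1.0 - np.sum(w * (y - mu) ** 2) / denom)


def _sqcorr_r2(y, mu, w) -> float:
    ybar, mbar = np.average(y, weights=w), np.average(mu, weights=w)
    cov = np.sum(w * (y - ybar) * (mu - mbar))
    vy = np.sum(w * (y - ybar) ** 2)
    vm = np.sum(w * (mu - mbar) ** 2)
    return float(cov**2 / (vy * vm)) if vy > 0 and vm > 0 else 0.0


def _pool_to_effect(outcome, index_name, per_imp, r2_full, r2_base, dfcom, extra=None):
    pooled = pool_estimates(per_imp, dfcom=dfcom)
    rf, rb = float(np.mean(r2_full)), float(np.mean(r2_base))
    return MarginalEffect(
        outcome=outcome,
        index_name=index_name,
        estimate=pooled.estimate,
        ci95=pooled.ci95(),
        se=pooled.se,
        p_value=pooled.p_value,
        partial_r2=rf - rb,
        r2_full=rf,
        r2_base=rb,
        extra=extra or {},
    )


def binary_validity(
    imputations,
    scores_per_imputation,
    outcome: str,
    index_name: str = "index",
    weight_col: str = "attrition_weight",
) -> MarginalEffect:
    """Pooled 1-SD average marginal effect of the index on a binary outcome.

    ``scores_per_imputation`` is one standardized score series per imputed
    copy (an :class:`~cati.weighting.IndexScores` is also accepted).
    """
    per_imp, r2f, r2b = [], [], []
    dfcom = None
    for copy, sc in zip(imputations, scores_per_imputation):
        score = sc.standardized if isinstance(sc, IndexScores) else pd.Series(sc)
        y = copy[outcome].to_numpy(float)
        if len(np.unique(y)) < 2:
            raise DataError(f"outcome {outcome!r} has no variation")
        w = copy[weight_col].to_numpy(float)
        demo = demographic_design(copy)
        X = add_constant(pd.concat([pd.Series(score.to_numpy(), index=copy.index, name="score"),
                                    demo], axis=1))
        fit = _fit_glm(X, y, w, "logit")
        ame, g = _ame_logit(fit)
        var = float(g @ fit.cov_model @ g)
        per_imp.append((ame, var))
        base = _fit_glm(add_constant(demo), y, w, "logit")
        r2f.append(_efron_r2(y, fit.mu, w))
        r2b.append(_efron_r2(y, base.mu, w))
        dfcom = len(y) - X.shape[1]
    return _pool_to_effect(outcome, index_name, per_imp, r2f, r2b, dfcom)


def earnings_validity(
    imputations,
    scores_per_imputation,
    outcome: str = "peak_earnings",
    index_name: str = "index",
    weight_col: str = "attrition_weight",
) -> MarginalEffect:
    """Pooled percent change in peak earnings per 1-SD increase in the index.

    Weighted Poisson regression with a robust sandwich covariance; the
    estimate is ``100 * (exp(beta) - 1)`` with a delta-method variance, and
    partial R^2 uses the squared-correlation definition.
    """
    per_imp, r2f, r2b, betas = [], [], [], []
    dfcom = None
    for copy, sc in zip(imputations, scores_per_imputation):
        score = sc.standardized if isinstance(sc, IndexScores) else pd.Series(sc)
        y = copy[outcome].to_numpy(float)
        if not np.any(y > 0):
            raise DataError("earnings are all zero")
        w = copy[weight_col].to_numpy(float)
        controls = pd.concat([demographic_design(copy), earnings_controls_design(copy)], axis=1)
        X = add_constant(pd.concat([pd.Series(score.to_numpy(), index=copy.index, name="score"),
                                    controls], axis=1))
        fit = _fit_glm(X, y, w, "poisson")
        j = fit.score_col
        b = fit.beta[j]
        vb = fit.cov_robust[j, j]
        pct = 100.0 * (np.exp(b) - 1.0)
        per_imp.append((pct, (100.0 * np.exp(b)) ** 2 * vb))
        betas.append(b)
        base = _fit_glm(add_constant(controls), y, w, "poisson")
        r2f.append(_sqcorr_r2(y, fit.mu, w))
        r2b.append(_sqcorr_r2(y, base.mu, w))
        dfcom = len(y) - X.shape[1]
    return _pool_to_effect(outcome, index_name, per_imp, r2f, r2b, dfcom,
                           extra={"beta_score": float(np.mean(betas))})


def equal_weight_index(components: pd.DataFrame, component_list=None) -> IndexScores:
    """Count-of-positives comparator index (equal weights), standardized."""
    names = list(component_list) if component_list is not None else list(components.columns)
    if not names:
        raise DataError("empty component list")
    missing = [n for n in names if n not in components.columns]
    if missing:
        raise DataError(f"component columns absent from data: {missing}")
    mat = components[names]
    if mat.isna().any().any():
        raise DataError("component matrix contains missing values; impute first")
    counts = mat.sum(axis=1)
    return IndexScores(values=counts, standardized=pd.Series(standardize(counts), index=mat.index))


def compare_indices(
    y,
    score_a,
    score_b,
    demographics: pd.DataFrame,
    weights=None,
    family: str = "logit",
    names: tuple = ("a", "b"),
    method: str = "stacked",
    n_boot: int = 999,
    seed: int = 0,
) -> ComparisonResult:
    """Test the difference between two indices' marginal effects on the
    same outcome and sample.

    The default method stacks the two estimating-equation systems and uses
    the joint sandwich covariance (cross block from the per-observation
    scores), so the shared sample is accounted for; ``method="bootstrap"``
    instead uses a seeded paired bootstrap.
    """
    y = np.asarray(y, dtype=float)
    sa = np.asarray(score_a.standardized if isinstance(score_a, IndexScores) else score_a, float)
    sb = np.asarray(score_b.standardized if isinstance(score_b, IndexScores) else score_b, float)
    if len(sa) != len(y) or len(sb) != len(y):
        raise DataError("indices must be fitted on identical samples")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if family != "logit":
        raise DataError("compare_indices currently supports the logit family")

    def one_ame(scores):
        X = add_constant(
            pd.concat(
                [pd.Series(scores, index=demographics.index, name="score"), demographics], axis=1
            )
        )
        fit = _fit_glm(X, y, w, "logit")
        ame, g = _ame_logit(fit)
        return fit, ame, g

    fit_a, ame_a, g_a = one_ame(sa)
    fit_b, ame_b, g_b = one_ame(sb)
    diff = ame_a - ame_b

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(y)
        diffs = np.empty(n_boot)
        for r in range(n_boot):
            idx = rng.integers(0, n, size=n)
            dboot = demographics.iloc[idx].reset_index(drop=True)
            yb, wb = y[idx], w[idx]

            def boot_ame(scores):
                X = add_constant(
                    pd.concat(
                        [pd.Series(scores[idx], index=dboot.index, name="score"), dboot], axis=1
                    )
                )
                fit = _fit_glm(X, yb, wb, "logit")
                return _ame_logit(fit)[0]

            diffs[r] = boot_ame(sa) - boot_ame(sb)
        se = float(diffs.std(ddof=1))
        p = float(2 * min((diffs <= 0).mean(), (diffs >= 0).mean()))
        p = min(1.0, max(p, 2.0 / (n_boot + 1)))
        return ComparisonResult((names[0], names[1]), float(diff), se, p, "bootstrap")

    Ha_inv = np.linalg.inv(fit_a.H)
    Hb_inv = np.linalg.inv(fit_b.H)
    V_aa = Ha_inv @ (fit_a.scores.T @ fit_a.scores) @ Ha_inv
    V_bb = Hb_inv @ (fit_b.scores.T @ fit_b.scores) @ Hb_inv
    V_ab = Ha_inv @ (fit_a.scores.T @ fit_b.scores) @ Hb_inv
    var = float(g_a @ V_aa @ g_a + g_b @ V_bb @ g_b - 2.0 * g_a @ V_ab @ g_b)
    var = max(var, 0.0)
    if var == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(diff) / np.sqrt(var)))
    return ComparisonResult((names[0], names[1]), float(diff), float(np.sqrt(var)), p, "stacked")


def compare_indices_mi(imputations, scores_a, scores_b, outcome, names=("a", "b"),
                       weight_col="attrition_weight", **kwargs) -> ComparisonResult:
    """Pool the stacked-comparison difference over imputations."""
    per_imp = []
    for copy, sa, sb in zip(imputations, scores_a, scores_b):
        res = compare_indices(
            copy[outcome].to_numpy(float), sa, sb, demographic_design(copy),
            weights=copy[weight_col].to_numpy(float), names=names, **kwargs,
        )
        per_imp.append((res.difference, res.se**2))
    pooled = pool_estimates(per_imp)
    return ComparisonResult(tuple(names), pooled.estimate, pooled.se, pooled.p_value,
                            "stacked+pooled")
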