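"""Two-step component selection against each subjective scale.

Step 1 — adaptive LASSO, once per imputed copy, without attrition weights.
A pilot ridge regression (defined even under the multicollinearity common
among candidate components) supplies adaptive penalty weights
``1 / |pilot|**gamma``; the penalized fit runs over a log-spaced penalty
grid on a seeded 80% training split and the penalty is chosen on the
held-out 20% — by default the sparsest fit whose held-out loss is within
one (paired) standard error of the minimum, since the raw minimizer of a
single validation split is known to overselect.  Demographic controls are
never penalized: they are concentrated out exactly by residualizing the outcome
and the component columns on the demographic design (the penalized problem
with an unpenalized block is equivalent to the lasso on those residuals).
A component survives this stage only if it is selected in at least half of
the m imputed copies (10 of 20 at the default m).

Step 2 — pooled, attrition-weighted backward elimination.  Weighted least
squares of the standardized scale on the surviving components plus
demographics is fitted in every copy and pooled; components are then
removed one at a time — wrong-signed components first (largest p first),
then any with pooled p > 0.25 — refitting after each removal until the
remaining set is clean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import lasso_path

from .design import add_constant, component_frame, demographic_design
from .imputation import ImputationSet, pool_estimates
from .weighting import SCALES, DataError, preprocess_scales

#: Expected coefficient sign for a positively framed (1 = good status)
#: component on each scale: positive for flourishing and life satisfaction,
#: negative for distress, worry and social anxiety.
DEFAULT_SIGN_EXPECTATIONS = {"fl": 1, "pd": -1, "wr": -1, "sa": -1, "ls": 1}

KEPT = "kept"
REMOVED_LASSO = "removed_lasso"
REMOVED_POST = "removed_post"


@dataclass
class SelectionMask:
    """Per-component selection status for one benchmark outcome."""

    outcome: str
    status: dict
    retention_counts: dict
    m: int
    threshold: int

    def kept(self) -> list:
        return [c for c, s in self.status.items() if s == KEPT]

    def validate(self) -> None:
        for c, s in self.status.items():
            if s == KEPT and self.retention_counts.get(c, 0) < self.threshold:
                raise DataError(f"component {c!r} kept below retention threshold")


@dataclass
class CoefficientMatrix:
    """Pooled coefficients of each scale's final equation (0 where removed).

    ``beta``, ``se`` and ``p`` are (scales x components) DataFrames;
    demographic coefficients are held separately in ``demographics``.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    p: pd.DataFrame
    masks: dict = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)

    def tidy(self) -> pd.DataFrame:
        """Long layout mirroring a component x outcome audit table."""
        rows = []
        for outcome in self.beta.index:
            mask = self.masks.get(outcome)
            for comp in self.beta.columns:
                status = mask.status.get(comp, KEPT) if mask else KEPT
                rows.append(
                    {
                        "component": comp,
                        "outcome": outcome,
                        "status": {KEPT: "kept", REMOVED_LASSO: "LASSO", REMOVED_POST: "POST"}[status],
                        "beta": self.beta.loc[outcome, comp],
                        "se": self.se.loc[outcome, comp],
                        "p": self.p.loc[outcome, comp],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class AdaptiveLassoFit:
    kept: frozenset
    alpha: float
    coefficients: pd.Series
    test_mse: np.ndarray
    alphas: np.ndarray


def _residualize(D_train, y_train, D_apply, y_apply):
    """Project out an unpenalized block, using train-fitted coefficients."""
    coef, *_ = np.linalg.lstsq(D_train, y_train, rcond=None)
    return y_train - D_train @ coef, y_apply - D_apply @ coef


def fit_adaptive_lasso(
    components: pd.DataFrame,
    demographics: pd.DataFrame,
    y,
    split_fraction: float = 0.2,
    seed: int = 0,
    n_alphas: int = 100,
    gamma: float = 1.0,
    pilot_ridge: float = 1e-2,
    alphas=None,
    penalty_rule: str = "1se",
) -> AdaptiveLassoFit:
    """Adaptive LASSO of a standardized outcome on 0/1 components with
    unpenalized demographic controls; penalty tuned on a held-out split.

    ``penalty_rule='1se'`` (default) picks the sparsest penalty whose
    held-out MSE is within one standard error of the minimum — the
    parsimony rule needed for the selection stage to control false
    inclusions; ``'min'`` picks the raw MSE minimizer, which is known to
    overselect under a single validation split.
    """
    y = np.asarray(y, dtype=float)
    names = list(components.columns)
    X = components.to_numpy(float)
    D = add_constant(demographics).to_numpy(float)
    n = len(y)
    if not 0.0 < split_fraction < 1.0:
        raise DataError("split_fraction must be in (0, 1)")

    keep_cols = []
    for i, nm in enumerate(names):
        if np.ptp(X[:, i]) == 0:
            warnings.warn(f"dropping constant component column {nm!r}", stacklevel=2)
        else:
            keep_cols.append(i)
    X = X[:, keep_cols]
    names = [names[i] for i in keep_cols]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(split_fraction * n)))
    test, train = perm[:n_test], perm[n_test:]

    y_tr, y_te = _residualize(D[train], y[train], D[test], y[test])
    X_tr = np.empty((len(train), X.shape[1]))
    X_te = np.empty((len(test), X.shape[1]))
    for i in range(X.shape[1]):
        X_tr[:, i], X_te[:, i] = _residualize(D[train], X[train, i], D[test], X[test, i])

    # pilot ridge estimates -> adaptive penalty weights 1/|pilot|^gamma
    k = X_tr.shape[1]
    A = X_tr.T @ X_tr + pilot_ridge * len(train) * np.eye(k)
    pilot = np.linalg.solve(A, X_tr.T @ y_tr)
    scale = np.abs(pilot) ** gamma
    active = scale > 0  # zero pilot => infinite penalty => excluded
    if not np.any(active):
        return AdaptiveLassoFit(frozenset(), np.inf, pd.Series(0.0, index=names),
                                np.array([]), np.array([]))

    Xs_tr = X_tr[:, active] * scale[active]
    Xs_te = X_te[:, active] * scale[active]
    x_mean, y_mean = Xs_tr.mean(axis=0), y_tr.mean()
    Xc, yc = Xs_tr - x_mean, y_tr - y_mean

    if alphas is None:
        alpha_max = np.max(np.abs(Xc.T @ yc)) / len(train)
        if alpha_max <= 0:
            alpha_max = 1.0
        alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3), n_alphas)
    alphas = np.sort(np.asarray(alphas, dtype=float))[::-1]

    _, coefs, _ = lasso_path(Xc, yc, alphas=alphas)
    pred = (Xs_te - x_mean) @ coefs + y_mean
    sqerr = (y_te[:, None] - pred) ** 2
    mse = sqerr.mean(axis=0)
    best = int(np.argmin(mse))
    if penalty_rule == "1se":
        # paired one-standard-error rule: the candidate and the minimizer
        # are scored on the same held-out observations, so the relevant
        # uncertainty is that of the per-observation loss *difference*
        diff = sqerr - sqerr[:, [best]]
        se_diff = diff.std(axis=0, ddof=1) / np.sqrt(len(y_te))
        within = np.flatnonzero(diff.mean(axis=0) <= se_diff)
        best = int(within[0])  # alphas are descending: sparsest qualifying fit
    elif penalty_rule != "min":
        raise DataError(f"unknown penalty_rule {penalty_rule!r}")

    beta_scaled = coefs[:, best]
    beta = np.zeros(k)
    beta[active] = beta_scaled * scale[active]
    coef_series = pd.Series(beta, index=names)
    kept = frozenset(coef_series.index[coef_series != 0.0])
    return AdaptiveLassoFit(kept, float(alphas[best]), coef_series, mse, alphas)


def aggregate_selection(kept_sets, candidates, outcome: str = "", threshold: int | None = None) -> SelectionMask:
    """Majority retention rule across imputations: a component survives the
    LASSO stage iff selected in at least ceil(m/2) of the m copies."""
    kept_sets = list(kept_sets)
    if not kept_sets:
        raise DataError("no per-imputation kept-sets supplied")
    m = len(kept_sets)
    if threshold is None:
        threshold = math.ceil(m / 2)
    counts = {c: sum(c in ks for ks in kept_sets) for c in candidates}
    status = {c: (KEPT if counts[c] >= threshold else REMOVED_LASSO) for c in candidates}
    return SelectionMask(outcome=outcome, status=status, retention_counts=counts, m=m,
                         threshold=threshold)


def _pooled_wls(imputations, outcome: str, kept: list, weight_col: str = "attrition_weight"):
    """Weighted least squares per copy, pooled per component coefficient."""
    per_param: dict = {c: [] for c in kept}
    demo_names = None
    demo_acc: dict = {}
    dfcom = None
    for copy in imputations:
        y = preprocess_scales(copy)[outcome].to_numpy()
        comps = component_frame(copy, kept)
        demo = demographic_design(copy)
        X = add_constant(pd.concat([comps, demo], axis=1))
        w = copy[weight_col].to_numpy(float)
        res = sm.WLS(y, X.to_numpy(float), weights=w).fit()
        dfcom = len(y) - X.shape[1]
        params = pd.Series(res.params, index=X.columns)
        bse = pd.Series(res.bse, index=X.columns)
        for c in kept:
            per_param[c].append((params[c], bse[c] ** 2))
        if demo_names is None:
            demo_names = ["const"] + list(demo.columns)
            demo_acc = {d: [] for d in demo_names}
        for d in demo_names:
            demo_acc[d].append((params[d], bse[d] ** 2))
    pooled = {c: pool_estimates(v, dfcom=dfcom) for c, v in per_param.items()}
    demo_pooled = {d: pool_estimates(v, dfcom=dfcom) for d, v in demo_acc.items()}
    return pooled, demo_pooled


def backward_eliminate(
    imputations,
    outcome: str,
    mask: SelectionMask,
    sign_expectations: dict | None = None,
    p_threshold: float = 0.25,
    weight_col: str = "attrition_weight",
):
    """One-at-a-time post-LASSO elimination under sign and p rules.

    Priority is deterministic: among wrong-signed components remove the one
    with the largest pooled p first; once all signs agree, remove the
    component with the largest pooled p above ``p_threshold``; refit and
    repeat.  Returns the updated mask, the pooled coefficient row for the
    survivors, pooled demographic coefficients, and the elimination trace.
    """
    signs = dict(sign_expectations or DEFAULT_SIGN_EXPECTATIONS)
    expected = signs.get(outcome, 1)
    mask = SelectionMask(mask.outcome or outcome, dict(mask.status), dict(mask.retention_counts),
                         mask.m, mask.threshold)
    trace = []
    pooled: dict = {}
    demo_pooled: dict = {}
    while True:
        kept = mask.kept()
        if not kept:
            trace.append("all components eliminated")
            return mask, {}, demo_pooled, trace
        pooled, demo_pooled = _pooled_wls(imputations, outcome, kept, weight_col)
        wrong = [c for c in kept if np.sign(pooled[c].estimate) not in (0.0, expected)]
        if wrong:
            victim = max(wrong, key=lambda c: pooled[c].p_value)
            reason = "wrong sign"
        else:
            weak = [c for c in kept if pooled[c].p_value > p_threshold]
            if not weak:
                break
            victim = max(weak, key=lambda c: pooled[c].p_value)
            reason = f"p={pooled[victim].p_value:.3f} > {p_threshold}"
        mask.status[victim] = REMOVED_POST
        trace.append(f"removed {victim} ({reason})")
    row = {c: pooled[c] for c in mask.kept()}
    return mask, row, demo_pooled, trace


def _substream(seed: int, *branch) -> int:
    return int(np.random.SeedSequence([seed, *branch]).generate_state(1)[0] % (2**31))


def select_components(
    imputations: ImputationSet,
    candidates,
    outcomes=SCALES,
    sign_expectations: dict | None = None,
    split_fraction: float = 0.2,
    seed: int = 0,
    n_alphas: int = 100,
    p_threshold: float = 0.25,
    gamma: float = 1.0,
    pilot_ridge: float = 1e-2,
    penalty_rule: str = "1se",
    log=None,
) -> CoefficientMatrix:
    """Run the full two-step selection for every benchmark outcome.

    The LASSO stage standardizes the outcome within each imputed copy, is
    unweighted, and uses a fresh seeded 80/20 split per copy; the backward
    elimination stage is attrition-weighted and pooled.
    """
    candidates = list(candidates)
    outcomes = list(outcomes)
    beta = pd.DataFrame(0.0, index=outcomes, columns=candidates)
    se = pd.DataFrame(0.0, index=outcomes, columns=candidates)
    pmat = pd.DataFrame(1.0, index=outcomes, columns=candidates)
    masks = {}
    demo_all = {}
    for j, outcome in enumerate(outcomes):
        kept_sets = []
        for k, copy in enumerate(imputations):
            y = preprocess_scales(copy)[outcome].to_numpy()
            comps = component_frame(copy, candidates)
            demo = demographic_design(copy)
            fit = fit_adaptive_lasso(
                comps, demo, y,
                split_fraction=split_fraction,
                seed=_substream(seed, j, k),
                n_alphas=n_alphas, gamma=gamma, pilot_ridge=pilot_ridge,
                penalty_rule=penalty_rule,
            )
            kept_sets.append(fit.kept)
        mask = aggregate_selection(kept_sets, candidates, outcome=outcome)
        mask, row, demo_pooled, trace = backward_eliminate(
            imputations, outcome, mask, sign_expectations, p_threshold
        )
        if log is not None:
            log(outcome, mask, trace)
        masks[outcome] = mask
        demo_all[outcome] = demo_pooled
        for c, est in row.items():
            beta.loc[outcome, c] = est.estimate
            se.loc[outcome, c] = est.se
            pmat.loc[outcome, c] = est.p_value
    return CoefficientMatrix(beta=beta, se=se, p=pmat, masks=masks, demographics=demo_all)
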