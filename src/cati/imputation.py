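"""Chained-equations multiple imputation and Rubin-rule pooling.

Missing component, scale and outcome cells are completed m times (default
20) by cycling per-variable conditional models: binary variables by
logistic draws, continuous variables by Bayesian normal-linear draws (peak
earnings on the log scale).  Every conditional model uses the
always-observed demographics and log attrition weight plus the current
values of all other imputable variables as predictors, which matches the
missing-at-random mechanism of the synthetic generator.  Draws are proper:
regression coefficients are perturbed by their estimated posterior
covariance before each prediction, so between-imputation variance reflects
model uncertainty rather than residual noise alone.

Estimates computed on each completed copy are combined with the standard
multiple-imputation rules: pooled estimate = mean; total variance = within
+ (1 + 1/m) x between; reference distribution a t with Barnard-Rubin
small-sample degrees of freedom when the complete-data degrees of freedom
are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .design import demographic_design
from .synthetic_cohort import missable_columns
from .weighting import DataError


@dataclass
class PooledEstimate:
    """A multiply-imputed estimate with its variance decomposition."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    p_value: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def ci95(self) -> tuple:
        if self.total_var == 0:
            return (self.estimate, self.estimate)
        q = stats.t.ppf(0.975, self.df) if np.isfinite(self.df) else stats.norm.ppf(0.975)
        return (self.estimate - q * self.se, self.estimate + q * self.se)


def pool_estimates(per_imputation, dfcom: float | None = None) -> PooledEstimate:
    """Combine per-imputation (estimate, variance) pairs.

    ``dfcom`` is the complete-data residual degrees of freedom; when given,
    the Barnard-Rubin adjusted degrees of freedom are used, otherwise the
    classic large-sample formula.
    """
    pairs = list(per_imputation)
    if len(pairs) < 2:
        raise DataError("pooling requires at least 2 imputations (between-variance undefined)")
    est = np.array([p[0] for p in pairs], dtype=float)
    var = np.array([p[1] for p in pairs], dtype=float)
    if np.any(var < 0):
        raise DataError("negative within-imputation variance")
    m = len(est)
    qbar = est.mean()
    within = var.mean()
    between = est.var(ddof=1)
    total = within + (1.0 + 1.0 / m) * between

    if total == 0.0:
        return PooledEstimate(qbar, within, between, total, np.inf, 1.0 if qbar == 0 else 0.0, m)
    if between == 0.0:
        df = float(dfcom) if dfcom is not None else np.inf
    else:
        r = (1.0 + 1.0 / m) * between / within if within > 0 else np.inf
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else float(m - 1)
        if dfcom is None:
            df = df_old
        else:
            lam = (1.0 + 1.0 / m) * between / total
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    t = qbar / np.sqrt(total)
    p = float(2 * (stats.t.sf(abs(t), df) if np.isfinite(df) else stats.norm.sf(abs(t))))
    return PooledEstimate(float(qbar), float(within), float(between), float(total), float(df), p, m)


@dataclass
class ImputationSet:
    """m completed copies of a cohort plus provenance."""

    copies: list
    seed: int
    n_iter: int
    variable_models: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.copies)

    def __iter__(self):
        return iter(self.copies)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k, copy in enumerate(self.copies):
            copy.to_csv(directory / f"imputation_{k + 1:02d}.csv", index=False)
        manifest = {
            "m": self.m,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "variable_models": self.variable_models,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ImputationSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        copies = [
            pd.read_csv(directory / f"imputation_{k + 1:02d}.csv") for k in range(manifest["m"])
        ]
        return cls(
            copies=copies,
            seed=manifest["seed"],
            n_iter=manifest["n_iter"],
            variable_models=manifest["variable_models"],
        )


def _classify(cohort: pd.DataFrame) -> dict:
    """Conditional-model family per imputable column."""
    models = {}
    for col in missable_columns(cohort):
        if col.startswith("comp_") or col.startswith("ever_"):
            models[col] = "binary"
        elif col == "peak_earnings":
            models[col] = "lognormal"
        else:
            models[col] = "normal"
    return models


def _ridge_logit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-4, max_iter: int = 30):
    """Ridge-stabilized logistic fit; returns (beta_hat, covariance)."""
    n, k = X.shape
    beta = np.zeros(k)
    eye = np.eye(k)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-6, None)
        A = X.T @ (X * w[:, None]) + ridge * eye
        step = np.linalg.solve(A, X.T @ (y - p) - ridge * beta)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-6, None)
    A = X.T @ (X * w[:, None]) + ridge * eye
    return beta, np.linalg.inv(A)


def _draw_continuous(X_obs, y_obs, X_mis, rng, ridge: float = 1e-8):
    """Proper Bayesian normal-linear imputation draw."""
    n, k = X_obs.shape
    A = X_obs.T @ X_obs + ridge * np.eye(k)
    beta_hat = np.linalg.solve(A, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - k, 1)
    rss = float(resid @ resid)
    sigma2 = rss / rng.chisquare(dof) if rss > 0 else 0.0
    cov = sigma2 * np.linalg.inv(A)
    beta = (
        rng.multivariate_normal(beta_hat, (cov + cov.T) / 2, method="eigh")
        if sigma2 > 0
        else beta_hat
    )
    return X_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(X_mis))


def _draw_binary(X_obs, y_obs, X_mis, rng):
    classes = np.unique(y_obs)
    if len(classes) == 1:
        return np.full(len(X_mis), classes[0])
    beta_hat, cov = _ridge_logit(X_obs, y_obs)
    beta = rng.multivariate_normal(beta_hat, (cov + cov.T) / 2, method="eigh")
    p = expit(X_mis @ beta)
    return (rng.random(len(X_mis)) < p).astype(float)


def impute_chained(
    cohort: pd.DataFrame, m: int = 20, seed: int = 0, n_iter: int = 10
) -> ImputationSet:
    """Multiply impute a cohort by chained equations.

    Demographics and attrition weights must be fully observed.  Returns m
    completed copies, bit-identical to the input at observed cells and
    deterministic for a fixed seed.  A variable with no observed values
    cannot be imputed and raises a :class:`DataError` naming it.
    """
    if m < 2:
        raise DataError("m must be >= 2")
    base_cols = ["age", "sex", "race_ethnicity", "attrition_weight"]
    if cohort[base_cols].isna().any().any():
        raise DataError("demographics and attrition weights must be fully observed")

    models = _classify(cohort)
    miss_counts = {c: int(cohort[c].isna().sum()) for c in models}
    targets = [c for c, cnt in sorted(miss_counts.items(), key=lambda kv: kv[1]) if cnt > 0]
    for c in targets:
        if cohort[c].notna().sum() == 0:
            raise DataError(f"variable {c!r} has no observed values and cannot be imputed")

    if not targets:
        return ImputationSet(copies=[cohort.copy() for _ in range(m)], seed=seed, n_iter=n_iter,
                             variable_models=models)

    base = demographic_design(cohort)
    base["log_weight"] = np.log(cohort["attrition_weight"].astype(float))
    base_mat = np.column_stack([np.ones(len(cohort)), base.to_numpy(float)])

    all_imp_cols = list(models)
    obs_mask = {c: cohort[c].notna().to_numpy() for c in targets}

    def transform(col, values):
        return np.log1p(np.maximum(values, 0.0)) if models[col] == "lognormal" else values

    def back_transform(col, values):
        if models[col] == "lognormal":
            return np.maximum(0.0, np.round(np.expm1(values)))
        return values

    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(m)]
    copies = []
    for k in range(m):
        rng = rngs[k]
        work = cohort.copy()
        # initialize missing cells from the observed empirical distribution
        for c in targets:
            obs_vals = work.loc[work[c].notna(), c].to_numpy(float)
            n_mis = int(work[c].isna().sum())
            work.loc[work[c].isna(), c] = rng.choice(obs_vals, size=n_mis, replace=True)
        for _ in range(n_iter):
            for c in targets:
                others = [o for o in all_imp_cols if o != c]
                X = np.column_stack(
                    [base_mat]
                    + [transform(o, work[o].to_numpy(float))[:, None] for o in others]
                )
                y = transform(c, work[c].to_numpy(float))
                obs = obs_mask[c]
                if models[c] == "binary":
                    drawn = _draw_binary(X[obs], y[obs], X[~obs], rng)
                else:
                    drawn = _draw_continuous(X[obs], y[obs], X[~obs], rng)
                    drawn = back_transform(c, drawn)
                col_vals = work[c].to_numpy(float)
                col_vals[~obs] = drawn
                work[c] = col_vals
        copies.append(work)
    return ImputationSet(copies=copies, seed=seed, n_iter=n_iter, variable_models=models)
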