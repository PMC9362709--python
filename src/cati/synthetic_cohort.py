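"""Synthetic child-cohort generator with known ground truth.

The restricted panel data used to derive hedonically weighted child
well-being indices (candidate 0/1 components observed in childhood, five
correlated subjective well-being scales observed in young adulthood,
attrition weights, and young-adult health/earnings outcomes) cannot be
redistributed.  This module generates cohorts with the same statistical
structure from an explicit data-generating model, so that every downstream
stage — imputation, selection, weighting, scoring, validity — can be tested
against analytic ground truth.

Model
-----
Each child carries a latent thriving factor ``u ~ N(0, 1)``.  Candidate
components are Bernoulli draws in *positive* framing (1 = good status,
e.g. "food secure"), optionally tilted by age.  Each subjective scale j is
generated per survey wave on its native range as::

    value = center_j + spread_j * (loading_j * u + sum_z effect_{j,z} * comp_z + noise)

with per-wave idiosyncratic noise, so that wave-averaging downstream
actually reduces noise.  Young-adult outcomes depend on an overall thriving
score combining the latent factor and the components' well-being
contributions; earnings are log-normal, rounded to dollars.

Because components are generated independently of ``u`` (conditionally on
age, which the pipeline always controls for), the regression coefficient of
a standardized scale on a component identifies ``effect_{j,z} / sd_j``, and
the index weights the full pipeline should recover are available in closed
form from :func:`true_weights`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .weighting import SCALES, LoadingVector, WeightVector

#: Direction in which each subjective scale points relative to well-being:
#: flourishing and life satisfaction increase with thriving, psychological
#: distress, economic worry and social anxiety decrease.
WELLBEING_SIGN = {"fl": 1.0, "pd": -1.0, "wr": -1.0, "sa": -1.0, "ls": 1.0}

RACE_LEVELS = ("white", "black", "latinx", "other")
HOUSEHOLD_LEVELS = ("head", "spouse", "other")


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class ComponentSpec:
    """One candidate index component, stored in positive framing.

    ``effects`` is the per-scale effect (on the standardized latent scale,
    ordered fl, pd, wr, sa, ls) of having positive status.  ``age_slope``
    tilts the prevalence with standardized age on the logit scale, which is
    the hook used to induce component–demographic correlation (and hence a
    detectable missing-at-random signature).  ``negative_label`` carries the
    deficit-framed display name often used in descriptive tables.
    """

    name: str
    group: str = "individual"  # "individual" | "contextual"
    prevalence: float = 0.5
    effects: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    age_slope: float = 0.0
    negative_label: str | None = None

    def validate(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"component {self.name!r}: prevalence {self.prevalence} not in [0, 1]")
        if self.group not in ("individual", "contextual"):
            raise ConfigError(f"component {self.name!r}: unknown group {self.group!r}")
        if len(self.effects) != len(SCALES):
            raise ConfigError(f"component {self.name!r}: expected {len(SCALES)} effects")


@dataclass
class ScaleSpec:
    """Generating model for one subjective scale.

    ``loading`` is the (signed) loading on the latent thriving factor;
    ``noise_sd`` the per-wave idiosyncratic standard deviation; ``waves``
    how many young-adulthood waves are observed; ``center``/``spread`` map
    the standardized latent value onto the scale's native range.  Discrete
    scales (e.g. a 1–5 life-satisfaction item) are rounded per wave and
    clipped to ``bounds``.
    """

    loading: float
    noise_sd: float = 1.0
    waves: int = 1
    center: float = 0.0
    spread: float = 1.0
    discrete: bool = False
    bounds: tuple | None = None

    def validate(self, name: str) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"scale {name!r}: noise_sd must be >= 0")
        if not 1 <= int(self.waves) <= 3:
            raise ConfigError(f"scale {name!r}: waves must be in 1..3")
        if self.spread <= 0:
            raise ConfigError(f"scale {name!r}: spread must be > 0")

    @property
    def noise_var_effective(self) -> float:
        """Variance (standardized-latent scale) of the wave-averaged noise,
        including the discretization variance of rounded scales."""
        v = self.noise_sd**2
        if self.discrete:
            v += (1.0 / self.spread) ** 2 / 12.0
        return v / int(self.waves)


@dataclass
class DemographicsModel:
    age_range: tuple = (19.0, 27.0)
    female_prop: float = 0.5
    race_probs: dict = field(
        default_factory=lambda: {"white": 0.45, "black": 0.35, "latinx": 0.12, "other": 0.08}
    )

    def validate(self) -> None:
        if not 0.0 <= self.female_prop <= 1.0:
            raise ConfigError("female_prop not in [0, 1]")
        if set(self.race_probs) != set(RACE_LEVELS):
            raise ConfigError(f"race_probs must have keys {RACE_LEVELS}")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("race_probs must sum to 1")
        if self.age_range[1] <= self.age_range[0]:
            raise ConfigError("age_range must be increasing")


@dataclass
class OutcomeModel:
    """Young-adult outcome models on the overall thriving score.

    Binary outcomes are deficit-coded (1 = ever fair/poor health, 1 = ever
    depressed), so their slopes should be negative: thriving protects.
    Earnings are ``round(exp(log_mean + slope * thriving + sd * N(0,1)))``,
    giving the long right tail (mean of order the SD) typical of peak
    earnings in panel data.  ``component_scale`` multiplies the components'
    contribution to the thriving score that drives the outcomes, relative
    to the latent factor's; raising it makes the (component-based) index
    more strongly predictive of the adult outcomes.
    """

    health_intercept: float = -1.45
    health_slope: float = -0.55
    depression_intercept: float = -0.95
    depression_slope: float = -0.50
    earnings_log_mean: float = 10.06
    earnings_slope: float = 0.16
    earnings_sd: float = 0.74
    component_scale: float = 1.0


@dataclass
class AttritionModel:
    """Log-linear attrition-weight generator (weights normalized to mean 1)."""

    age_coef: float = 0.2
    female_coef: float = 0.15
    sd: float = 0.3

    def validate(self) -> None:
        if self.sd < 0:
            raise ConfigError("attrition sd must be >= 0")


@dataclass
class SimConfig:
    """Full data-generating configuration for one synthetic cohort."""

    n_children: int
    components: list = field(default_factory=list)
    scales: dict = field(default_factory=dict)  # name -> ScaleSpec, keys == SCALES
    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    outcomes: OutcomeModel = field(default_factory=OutcomeModel)
    attrition: AttritionModel = field(default_factory=AttritionModel)
    missing_rate: float = 0.0
    missing_cell_rate: float = 0.25
    missing_coefs: dict = field(
        default_factory=lambda: {"age": 0.4, "female": -0.2, "log_weight": 0.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_children < 1:
            raise ConfigError("n_children must be >= 1")
        if tuple(self.scales) and tuple(self.scales) != tuple(SCALES):
            raise ConfigError(f"scales must be exactly {SCALES} in order")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0.0 < self.missing_cell_rate <= 1.0:
            raise ConfigError("missing_cell_rate must be in (0, 1]")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ConfigError("component names must be unique")
        for c in self.components:
            c.validate()
        for name, s in self.scales.items():
            s.validate(name)
        self.demographics.validate()
        self.attrition.validate()

    # -- introspection -------------------------------------------------
    @property
    def component_names(self) -> list:
        return [c.name for c in self.components]

    def component_groups(self) -> dict:
        return {c.name: c.group for c in self.components}

    def effects_matrix(self) -> np.ndarray:
        """(n_components, 5) matrix of per-scale effects."""
        return np.array([c.effects for c in self.components], dtype=float).reshape(
            len(self.components), len(SCALES)
        )

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for c in d["components"]:
            c["effects"] = list(c["effects"])
        for s in d["scales"].values():
            if s["bounds"] is not None:
                s["bounds"] = list(s["bounds"])
        d["demographics"]["age_range"] = list(d["demographics"]["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["components"] = [
            ComponentSpec(**{**c, "effects": tuple(c["effects"])}) for c in d["components"]
        ]
        d["scales"] = {
            k: ScaleSpec(**{**s, "bounds": tuple(s["bounds"]) if s["bounds"] else None})
            for k, s in d["scales"].items()
        }
        demo = dict(d["demographics"])
        demo["age_range"] = tuple(demo["age_range"])
        d["demographics"] = DemographicsModel(**demo)
        d["outcomes"] = OutcomeModel(**d["outcomes"])
        d["attrition"] = AttritionModel(**d["attrition"])
        return cls(**d)


def _age_z(age: np.ndarray, demographics: DemographicsModel) -> np.ndarray:
    lo, hi = demographics.age_range
    mid = 0.5 * (lo + hi)
    sd = (hi - lo) / math.sqrt(12.0)  # SD of the uniform age distribution
    return (age - mid) / sd


def thriving_contributions(config: SimConfig) -> np.ndarray:
    """Per-component contribution to the overall thriving score.

    Projects each component's per-scale effect vector onto the well-being
    direction (fl, ls positive; pd, wr, sa negative), so that a component
    that raises flourishing and lowers distress contributes positively.
    """
    signs = np.array([WELLBEING_SIGN[s] for s in SCALES])
    return config.effects_matrix() @ signs / len(SCALES)


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw one fully observed cohort (missingness is applied separately)."""
    config.validate()
    if not config.scales:
        raise ConfigError("config.scales must define all five scales")
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    demo = config.demographics

    age = rng.uniform(*demo.age_range, size=n)
    female = rng.random(n) < demo.female_prop
    race = rng.choice(RACE_LEVELS, size=n, p=[demo.race_probs[r] for r in RACE_LEVELS])
    agez = _age_z(age, demo)

    u = rng.standard_normal(n)

    comp = {}
    for c in config.components:
        if c.age_slope == 0.0 or c.prevalence in (0.0, 1.0):
            p = np.full(n, c.prevalence)
        else:
            p = expit(logit(c.prevalence) + c.age_slope * agez)
        comp[c.name] = (rng.random(n) < p).astype(float)
    comp_matrix = (
        np.column_stack([comp[c.name] for c in config.components])
        if config.components
        else np.zeros((n, 0))
    )
    effects = config.effects_matrix()

    data = {"child_id": np.arange(1, n + 1), "age": age}
    data["sex"] = np.where(female, "female", "male")
    data["race_ethnicity"] = race
    for name, arr in comp.items():
        data[f"comp_{name}"] = arr

    for j, scale in enumerate(SCALES):
        spec = config.scales[scale]
        signal = spec.loading * u
        if len(config.components):
            signal = signal + comp_matrix @ effects[:, j]
        for w in range(int(spec.waves)):
            value = spec.center + spec.spread * (signal + rng.normal(0.0, spec.noise_sd, n))
            if spec.discrete:
                value = np.round(value)
            if spec.bounds is not None:
                value = np.clip(value, *spec.bounds)
            data[f"{scale}_w{w + 1}"] = value

    # attrition weights (never missing, strictly positive, mean 1)
    att = config.attrition
    lw = att.age_coef * agez + att.female_coef * female + rng.normal(0.0, att.sd, n)
    weight = np.exp(lw)
    data["attrition_weight"] = weight / weight.mean()

    # young-adult outcomes on the overall thriving score
    g = thriving_contributions(config)
    prev = np.array([c.prevalence for c in config.components])
    om = config.outcomes
    thriving = u + (
        om.component_scale * ((comp_matrix - prev) @ g) if len(config.components) else 0.0
    )
    data["ever_fair_poor_health"] = (
        rng.random(n) < expit(om.health_intercept + om.health_slope * thriving)
    ).astype(float)
    data["ever_depressed"] = (
        rng.random(n) < expit(om.depression_intercept + om.depression_slope * thriving)
    ).astype(float)
    log_earn = om.earnings_log_mean + om.earnings_slope * thriving + rng.normal(0.0, om.earnings_sd, n)
    data["peak_earnings"] = np.maximum(0.0, np.round(np.exp(log_earn)))

    # earnings-model controls
    data["years_observed_20_29"] = rng.integers(4, 11, size=n).astype(float)
    data["enrolled_at_peak"] = (rng.random(n) < 0.25).astype(float)
    data["household_position"] = rng.choice(HOUSEHOLD_LEVELS, size=n, p=[0.60, 0.15, 0.25])

    return pd.DataFrame(data)


def missable_columns(cohort: pd.DataFrame) -> list:
    """Columns eligible for missingness: components, scale waves, outcomes."""
    cols = [c for c in cohort.columns if c.startswith("comp_")]
    cols += [c for c in cohort.columns if any(c.startswith(f"{s}_w") for s in SCALES)]
    cols += [c for c in ("ever_fair_poor_health", "ever_depressed", "peak_earnings") if c in cohort]
    return cols


def apply_missingness(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Blank cells under a missing-at-random mechanism.

    Row-level missingness propensity is a logistic function of standardized
    age, sex and log attrition weight only — all always-observed — so the
    imputation models downstream are correctly specifiable.  The intercept
    is calibrated so the expected fraction of rows with at least one
    missing cell equals ``config.missing_rate``; within a selected row each
    eligible cell goes missing with ``config.missing_cell_rate`` (at least
    one forced).
    """
    config.validate()
    if config.missing_rate == 0.0:
        return cohort.copy()
    out = cohort.copy()
    n = len(out)
    agez = _age_z(out["age"].to_numpy(), config.demographics)
    female = (out["sex"] == "female").to_numpy(float)
    lp = (
        config.missing_coefs.get("age", 0.0) * agez
        + config.missing_coefs.get("female", 0.0) * female
        + config.missing_coefs.get("log_weight", 0.0) * np.log(out["attrition_weight"].to_numpy())
    )
    target = config.missing_rate
    intercept = brentq(lambda a: expit(a + lp).mean() - target, -30.0, 30.0)
    rng = np.random.default_rng([config.seed, 104729])
    rows = np.flatnonzero(rng.random(n) < expit(intercept + lp))

    cols = missable_columns(out)
    if not cols:
        raise ConfigError("cohort has no columns eligible for missingness")
    mask = rng.random((rows.size, len(cols))) < config.missing_cell_rate
    empty = ~mask.any(axis=1)
    mask[empty, rng.integers(0, len(cols), size=int(empty.sum()))] = True
    values = out[cols].to_numpy(float)
    sub = values[rows]
    sub[mask] = np.nan
    values[rows] = sub
    out[cols] = values
    return out


# ---------------------------------------------------------------------------
# Analytic ground truth
# ---------------------------------------------------------------------------

def analytic_scale_covariance(config: SimConfig) -> np.ndarray:
    """Model-implied 5x5 covariance of the wave-averaged standardized-latent
    scale values (before the native-range affine map, which cancels under
    downstream z-scoring).

    Assumes components are mutually independent (age slopes of zero); with
    mild age tilting it remains a close approximation.
    """
    lam = np.array([config.scales[s].loading for s in SCALES])
    cov = np.outer(lam, lam)
    if config.components:
        E = config.effects_matrix()  # (Z, 5)
        p = np.array([c.prevalence for c in config.components])
        cov = cov + E.T @ (E * (p * (1 - p))[:, None])
    cov = cov + np.diag([config.scales[s].noise_var_effective for s in SCALES])
    return cov


def analytic_first_pc(config: SimConfig) -> LoadingVector:
    """First principal component of the model-implied scale correlation matrix."""
    cov = analytic_scale_covariance(config)
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise ConfigError("a scale has zero model-implied variance")
    corr = cov / np.outer(sd, sd)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    first = eigvecs[:, 0]
    if first[SCALES.index("fl")] < 0:
        first = -first
    return LoadingVector(loadings=pd.Series(first, index=list(SCALES)), eigenvalues=eigvals)


def true_weights(config: SimConfig, include: list | None = None) -> WeightVector:
    """Normalized index weights implied by the generating model.

    Applies the double-weighting rule — mean over scales of |loading x
    standardized regression coefficient|, normalized to sum 1 — to the
    config's true effects and the analytic first-PC loadings, giving the
    ground truth that the full estimation pipeline should recover.
    """
    names = include if include is not None else config.component_names
    if not names:
        raise ConfigError("no components to weight")
    idx = [config.component_names.index(nm) for nm in names]
    E = config.effects_matrix()[idx]  # (Z, 5)
    cov = analytic_scale_covariance(config)
    sd = np.sqrt(np.diag(cov))
    beta = E / sd[None, :]  # standardized-outcome coefficients
    loadings = analytic_first_pc(config).loadings.to_numpy()
    raw = np.abs(beta * loadings[None, :]).mean(axis=1)
    if not np.any(raw > 0):
        raise ConfigError("all true effects are zero: weights undefined")
    return WeightVector(
        raw=pd.Series(raw, index=names), normalized=pd.Series(raw / raw.sum(), index=names)
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# (name, group, positive prevalence, effects (fl, pd, wr, sa, ls), deficit label)
# Prevalences are positive-framed complements of descriptive rates typical of
# a US longitudinal child cohort; effect sizes follow the magnitudes seen in
# published hedonic-weighting regressions of standardized subjective scales.
_PSID_LIKE_COMPONENTS = [
    ("food_secure", "individual", 0.867, (0.168, -0.166, -0.228, -0.177, 0.171), "Ever Food Insecure"),
    ("attended_preschool", "individual", 0.376, (0.0, -0.102, 0.0, 0.0, 0.0), "Never in Preschool"),
    ("graduated_hs_on_time", "individual", 0.800, (0.274, -0.224, -0.357, -0.171, 0.273), "Didn't Graduate High School on Time"),
    ("math_proficient", "individual", 0.244, (0.0, 0.0, -0.121, -0.118, 0.0), "Ever Nonproficient in Math"),
    ("reading_proficient", "individual", 0.265, (0.163, -0.067, 0.0, 0.0, 0.0), "Ever Nonproficient in Reading"),
    ("non_low_birthweight", "individual", 0.729, (0.123, 0.0, -0.096, 0.0, 0.0), "Low Birthweight"),
    ("non_obese", "individual", 0.673, (0.0, 0.0, -0.084, 0.0, 0.0), "Ever Obese"),
    ("not_fair_poor_health", "individual", 0.939, (0.0, 0.0, 0.0, -0.136, 0.0), "Ever in Fair/Poor Health"),
    ("didnt_smoke", "individual", 0.742, (0.236, -0.224, -0.267, 0.0, 0.104), "Ever Smoked Regularly"),
    ("didnt_drink", "individual", 0.823, (0.0, 0.0, 0.0, 0.0, 0.0), "Ever Drank Regularly"),
    ("didnt_try_marijuana", "individual", 0.501, (0.0, -0.130, 0.0, 0.0, 0.192), "Tried Marijuana"),
    ("never_pregnant", "individual", 0.753, (0.0, 0.0, 0.0, 0.0, 0.0), "Ever Pregnant"),
    ("never_arrested", "individual", 0.835, (0.0, 0.0, 0.0, 0.0, 0.141), "Ever Arrested"),
    ("never_housing_burdened", "contextual", 0.395, (0.06, -0.05, -0.09, 0.0, 0.05), "Ever in a Housing Burdened Household"),
    ("never_household_poverty", "contextual", 0.538, (0.09, -0.08, -0.14, -0.05, 0.08), "Ever in Household Poverty"),
    ("never_parent_unemployed", "contextual", 0.483, (0.05, -0.05, -0.10, 0.0, 0.04), "Ever in a Household with Parent Unemployed"),
    ("family_never_moved", "contextual", 0.183, (0.04, 0.0, -0.05, 0.0, 0.0), "Family Ever Moved"),
    ("parent_hs_degree", "contextual", 0.735, (0.07, -0.06, -0.08, 0.0, 0.05), "Ever in a Household Where No Parent Had High School Degree"),
    ("married_head", "contextual", 0.262, (0.05, -0.04, -0.06, 0.0, 0.04), "Ever in Household With Unmarried Head"),
]

# Native centers/spreads follow descriptive statistics typical of the scales:
# flourishing-style positive mental health, K-6 distress, days-per-week worry
# and social-anxiety scores, and a 1-5 life-satisfaction item.
_PSID_LIKE_SCALES = {
    "fl": dict(sign=1, center=13.65, spread=2.06, waves=2),
    "pd": dict(sign=-1, center=5.04, spread=3.15, waves=2),
    "wr": dict(sign=-1, center=3.51, spread=1.35, waves=2),
    "sa": dict(sign=-1, center=3.36, spread=1.22, waves=2),
    "ls": dict(sign=1, center=2.26, spread=0.67, waves=3, discrete=True, bounds=(1.0, 5.0)),
}

#: Magnitude of the latent loading shared by all five scales in the preset;
#: chosen so the first eigenvalue of the scale correlation matrix lands near
#: 2.6 of 5 (roughly half the shared variance) once component effects are
#: included.  Per-wave noise keeps each scale's total latent-metric variance
#: near 1.
_PSID_LIKE_LOADING = 0.63


def psid_like_config(n_children: int = 5000, seed: int = 0, missing_rate: float = 0.40) -> SimConfig:
    """Preset emulating the descriptive structure of the restricted panel:
    13 individual + 6 contextual components at realistic prevalences, five
    correlated scales whose first principal component explains roughly half
    their variance, ~40% of rows with a missing cell, and linked outcomes."""
    components = [
        ComponentSpec(
            name=nm, group=grp, prevalence=prev, effects=eff, age_slope=0.15, negative_label=lab
        )
        for nm, grp, prev, eff, lab in _PSID_LIKE_COMPONENTS
    ]
    scales = {}
    for name, s in _PSID_LIKE_SCALES.items():
        loading = s["sign"] * _PSID_LIKE_LOADING
        # per-wave noise sized so the *wave-averaged* noise variance is
        # 1 - loading^2, keeping the averaged scale near unit variance
        scales[name] = ScaleSpec(
            loading=loading,
            noise_sd=math.sqrt(s["waves"] * (1.0 - _PSID_LIKE_LOADING**2)),
            waves=s["waves"],
            center=s["center"],
            spread=s["spread"],
            discrete=s.get("discrete", False),
            bounds=s.get("bounds"),
        )
    return SimConfig(
        n_children=n_children,
        components=components,
        scales=scales,
        missing_rate=missing_rate,
        seed=seed,
    )


#: Per-scale direction shared by all signal components in the recovery
#: preset (fl, pd, wr, sa, ls).  With one shared direction, the true
#: normalized weights are exactly proportional to the per-component
#: magnitudes, which makes recovery failures easy to localize.
_RECOVERY_DIRECTION = (1.0, -0.85, -1.05, -0.60, 0.90)

_RECOVERY_SIGNAL = [
    # (magnitude, prevalence); the smallest magnitude keeps every true
    # per-scale coefficient several estimation standard errors above zero
    # at the preset cohort size, so signal and null components are
    # statistically separable by design
    (0.35, 0.85), (0.28, 0.60), (0.24, 0.75), (0.20, 0.40), (0.18, 0.55),
    (0.16, 0.70), (0.15, 0.30), (0.13, 0.65), (0.12, 0.50), (0.11, 0.45),
    (0.10, 0.80),
]

_RECOVERY_NULL_PREVALENCES = (0.2, 0.35, 0.5, 0.65, 0.8)


def recovery_preset(n_children: int = 20000, seed: int = 0) -> SimConfig:
    """Study conditions for end-to-end parameter recovery.

    Eleven signal components whose per-scale effects all share one
    direction (true normalized weights proportional to the per-component
    magnitudes 0.30 down to 0.03), five null components, realistic scale
    model, and no missingness, so the estimation pipeline can be compared
    against :func:`true_weights` directly.
    """
    direction = np.array(_RECOVERY_DIRECTION)
    components = [
        ComponentSpec(name=f"signal_{i + 1:02d}", prevalence=prev,
                      effects=tuple(mag * direction))
        for i, (mag, prev) in enumerate(_RECOVERY_SIGNAL)
    ]
    components += [
        ComponentSpec(name=f"null_{i + 1}", prevalence=prev)
        for i, prev in enumerate(_RECOVERY_NULL_PREVALENCES)
    ]
    base = psid_like_config(n_children=n_children, seed=seed, missing_rate=0.0)
    return SimConfig(
        n_children=n_children,
        components=components,
        scales=base.scales,
        missing_rate=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path: str | Path, config: SimConfig | None = None) -> None:
    """Write the cohort CSV plus a JSON sidecar of the generating config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(".config.json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2))


def read_cohort(path: str | Path):
    """Read a cohort CSV (and its config sidecar if present).

    Returns ``(cohort, config_or_None)``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".config.json")
    config = SimConfig.from_dict(json.loads(sidecar.read_text())) if sidecar.exists() else None
    return df, config
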