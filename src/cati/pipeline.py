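"""End-to-end orchestration: impute -> select -> weight -> score -> validate.

The pipeline consumes a child-level cohort (generated or read from CSV),
produces the normalized component weights, per-respondent index scores and
the predictive-validity report, and records a manifest of seeds and
configuration for reproducibility.  All randomness flows from one master
seed through named substreams, so identical configuration yields identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .design import component_frame
from .imputation import ImputationSet, impute_chained
from .selection import CoefficientMatrix, select_components
from .synthetic_cohort import ConfigError, SimConfig
from .validity import (
    binary_validity,
    compare_indices_mi,
    earnings_validity,
    equal_weight_index,
)
from .weighting import (
    SCALES,
    DataError,
    IndexScores,
    WeightVector,
    compute_weights,
    pca_from_imputations,
    preprocess_scales,
    score_index,
)

BINARY_OUTCOMES = ("ever_fair_poor_health", "ever_depressed")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``inclusion`` selects which candidate components enter: the default
    uses individual-level components only (contextual determinants are
    causes of well-being, not outcome indicators of it);
    ``individual+contextual`` admits both; ``custom`` uses
    ``custom_components`` verbatim.
    """

    m: int = 20
    seed: int = 0
    inclusion: str = "individual"  # individual | individual+contextual | custom
    custom_components: list | None = None
    benchmarks: tuple = SCALES
    n_iter_impute: int = 10
    split_fraction: float = 0.2
    n_alphas: int = 100
    penalty_rule: str = "1se"  # '1se' | 'min'
    p_threshold: float = 0.25
    sign_expectations: dict | None = None
    run_validity: bool = True
    compare_equal_weight: bool = True

    def validate(self) -> None:
        if self.inclusion not in ("individual", "individual+contextual", "custom"):
            raise ConfigError(f"unknown inclusion mode {self.inclusion!r}")
        if self.inclusion == "custom" and not self.custom_components:
            raise ConfigError("custom inclusion mode requires custom_components")
        if not self.benchmarks:
            raise ConfigError("benchmark set must be non-empty")
        if self.m < 2:
            raise ConfigError("m must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["benchmarks"] = list(self.benchmarks)
        return d


@dataclass
class PipelineResult:
    imputations: ImputationSet
    coefficients: CoefficientMatrix
    loadings: object
    weights: WeightVector
    scores: IndexScores
    scores_per_imputation: list
    validity: dict
    comparisons: list
    manifest: dict


def _substream(seed: int, tag: str) -> int:
    h = int.from_bytes(hashlib.sha256(f"{seed}:{tag}".encode()).digest()[:4], "big")
    return h % (2**31)


def candidate_components(cohort: pd.DataFrame, config: PipelineConfig,
                         groups: dict | None = None) -> list:
    """Resolve the candidate component list under the inclusion mode.

    ``groups`` maps component name -> 'individual' | 'contextual'; without
    it every component column is treated as individual-level.
    """
    all_names = list(component_frame(cohort).columns)
    if config.inclusion == "custom":
        missing = [c for c in config.custom_components if c not in all_names]
        if missing:
            raise ConfigError(f"custom components not in cohort: {missing}")
        return list(config.custom_components)
    groups = groups or {}
    if config.inclusion == "individual":
        return [c for c in all_names if groups.get(c, "individual") == "individual"]
    return all_names


def run_pipeline(cohort: pd.DataFrame, config: PipelineConfig | None = None,
                 sim_config: SimConfig | None = None, log=None) -> PipelineResult:
    """Execute the full index-construction and validation pipeline."""
    config = config or PipelineConfig()
    config.validate()
    groups = sim_config.component_groups() if sim_config is not None else None
    candidates = candidate_components(cohort, config, groups)
    if not candidates:
        raise DataError("no candidate components in cohort")

    imputations = impute_chained(
        cohort, m=config.m, seed=_substream(config.seed, "imputation"),
        n_iter=config.n_iter_impute,
    )

    coefficients = select_components(
        imputations, candidates,
        outcomes=config.benchmarks,
        sign_expectations=config.sign_expectations,
        split_fraction=config.split_fraction,
        seed=_substream(config.seed, "lasso-splits"),
        n_alphas=config.n_alphas,
        penalty_rule=config.penalty_rule,
        p_threshold=config.p_threshold,
        log=log,
    )

    loadings = pca_from_imputations([preprocess_scales(c, config.benchmarks)
                                     for c in imputations])
    weights = compute_weights(loadings, coefficients)

    scores_per_imp = [score_index(component_frame(c, candidates), weights)
                      for c in imputations]
    mean_raw = pd.concat([s.values for s in scores_per_imp], axis=1).mean(axis=1)
    scores = IndexScores(
        values=mean_raw,
        standardized=(mean_raw - mean_raw.mean()) / mean_raw.std(ddof=1),
    )

    validity = {}
    comparisons = []
    if config.run_validity:
        for outcome in BINARY_OUTCOMES:
            validity[outcome] = binary_validity(imputations, scores_per_imp, outcome,
                                                index_name="cati")
        validity["peak_earnings"] = earnings_validity(imputations, scores_per_imp,
                                                      index_name="cati")

    if config.run_validity and config.compare_equal_weight:
        equal_per_imp = [equal_weight_index(component_frame(c, candidates))
                         for c in imputations]
        for outcome in BINARY_OUTCOMES:
            validity[f"{outcome}:equal_weight"] = binary_validity(
                imputations, equal_per_imp, outcome, index_name="equal_weight")
            comparisons.append(
                compare_indices_mi(imputations, scores_per_imp, equal_per_imp, outcome,
                                   names=("cati", "equal_weight")))
        validity["peak_earnings:equal_weight"] = earnings_validity(
            imputations, equal_per_imp, index_name="equal_weight")

    manifest = {
        "config": config.to_dict(),
        "candidates": candidates,
        "n": int(len(cohort)),
        "seeds": {"imputation": _substream(config.seed, "imputation"),
                  "lasso-splits": _substream(config.seed, "lasso-splits")},
        "weights_sha256": hashlib.sha256(
            weights.normalized.round(12).to_csv().encode()).hexdigest(),
    }
    return PipelineResult(imputations, coefficients, loadings, weights, scores,
                          scores_per_imp, validity, comparisons, manifest)


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write weights, scores, coefficient audit table, validity report and
    manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.weights.to_frame().rename_axis("component").to_csv(out / "weights.csv")
    ids = result.imputations.copies[0].get("child_id", pd.Series(result.scores.values.index))
    pd.DataFrame({"child_id": ids,
                  "score": result.scores.values,
                  "score_standardized": result.scores.standardized}).to_csv(
        out / "scores.csv", index=False)
    result.coefficients.tidy().to_csv(out / "coefficients.csv", index=False)
    report = {k: v.to_dict() for k, v in result.validity.items()}
    report["comparisons"] = [dataclasses.asdict(c) for c in result.comparisons]
    (out / "validity.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    lines = ["# Index construction report", "", "## Normalized weights", ""]
    for name, wv in result.weights.normalized.sort_values(ascending=False).items():
        lines.append(f"- {name}: {wv:.3f}")
    lines += ["", "## Predictive validity (1-SD marginal effects)", ""]
    for key, eff in result.validity.items():
        lines.append(
            f"- {key} [{eff.index_name}]: {eff.estimate:.3f} "
            f"(95% CI {eff.ci95[0]:.3f} to {eff.ci95[1]:.3f}; partial R2 {eff.partial_r2:.3f})"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")


def golden_check(tolerance: float = 0.005) -> dict:
    """Recompute the published CATI 1.0 weights from the published inputs.

    Applies the double-weighting rule to the reference first-PC loadings
    and coefficient matrix and compares every normalized weight to its
    published value.  Report-only: returns per-component deltas, the
    top-three share, and an overall pass flag.
    """
    weights = compute_weights(reference.reference_loadings(),
                              reference.reference_coefficients())
    rows = {}
    ok = True
    for name, published in reference.REFERENCE_WEIGHTS.items():
        got = float(weights.normalized[name])
        delta = got - published
        rows[name] = {"computed": got, "published": published, "delta": delta,
                      "within_tolerance": abs(delta) <= tolerance}
        ok = ok and abs(delta) <= tolerance
    top3 = float(weights.normalized.nlargest(3).sum())
    return {
        "weights": rows,
        "sum_of_weights": float(weights.normalized.sum()),
        "top3_share": top3,
        "top3_published": reference.REFERENCE_TOP3_SHARE,
        "tolerance": tolerance,
        "passed": ok,
    }
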