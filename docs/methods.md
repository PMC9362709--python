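# Methods

This note documents the models, estimation procedures and design choices
behind the package, in the spirit of the methods documentation shipped by
statistical packages: what is computed, under which assumptions, with which
defaults, and what the bundled synthetic data can and cannot demonstrate.

## The index model

The package constructs a composite index of child and adolescent well-being
from binary *outcome indicators* ("components", always coded in positive
framing: 1 = good status, e.g. food secure, graduated high school on time).
Component weights are *hedonic*: they are derived from the components'
regression relationship to five subjective well-being scales observed in
young adulthood — flourishing (fl), Kessler K-6 psychological distress (pd),
economic worry (wr), social anxiety (sa) and life satisfaction (ls).

Each scale is averaged within person across survey waves, z-scored, and
regressed on the candidate components plus demographic controls (continuous
age, sex, race/ethnicity). After model selection (below), the five
coefficient vectors are aggregated by *double weighting*: with first
principal-component loadings `l_j` of the five scales and pooled
coefficients `beta[j, z]` (0 where component z was removed from scale j's
equation),

    W_z        = (1/5) * sum_j | l_j * beta[j, z] |
    CompWght_z = W_z / sum_z W_z

and a respondent's index score is `sum_z CompWght_z * Comp[i, z]`, which
lies in [0, 1]. The absolute value is essential, not cosmetic: the
deficit-pointing scales (pd, wr, sa) have negative loadings and negative
coefficients for positively framed components, so without it their products
would cancel the fl/ls terms rather than reinforce them. The divisor stays
at 5 even for components that survive in only one equation — removal means
a zero coefficient, not a smaller denominator. Only the first principal
component is used; a warning is emitted if the second eigenvalue of the
scale correlation matrix also exceeds 1 (Kaiser criterion), since the
single-component design would then be questionable.

The main specification restricts components to individual-level outcome
indicators. Contextual determinants (household poverty, parental
unemployment, …) are causes of well-being rather than manifestations of it;
they are carried as a separate class and admitted only under the
`individual+contextual` inclusion mode.

## Model selection

Selection runs once per scale, in two steps.

**Step 1 — adaptive LASSO per imputation, unweighted.** Within each imputed
copy, the standardized scale is regressed on the components with an L1
penalty whose per-component weights are `1/|pilot|` (gamma = 1), the pilot
being a ridge regression with a small fixed penalty (ridge rather than OLS
because candidate components can be collinear, and ridge pilots are always
defined). Demographic controls are never penalized; they are concentrated
out exactly by residualizing the outcome and the component columns on the
demographic design, which is algebraically equivalent to leaving the block
unpenalized. The penalty is tuned on a seeded 80/20 train/validation split
(re-drawn per imputation from derived seeds) over 100 log-spaced penalties
spanning three decades below the smallest all-zero penalty.

*Penalty choice.* The default is a **paired one-standard-error rule**: take
the penalty minimizing held-out MSE, then move to the sparsest penalty
whose held-out loss is within one standard error of that minimum — where
the standard error is computed on the *per-observation difference* of
squared errors, since both fits are scored on the same held-out rows.
The raw minimizer (`penalty_rule="min"`) is retained as an option but is
not the default: with a single validation split the MSE curve is flat and
noisy below the point where the real predictors have entered, and the raw
argmin wanders into that region, dragging spurious components along. In
repeated trials with a pure-noise outcome (n = 2,000, 13 candidates), the
raw minimizer admitted ~4 spurious components per fit — a behaviour we
confirmed is intrinsic to the rule, not to this implementation, by
reproducing it with an independent R `glmnet` adaptive-LASSO fit on the
same data — while the paired 1-SE rule admits essentially none and still
retains a planted standardized effect of 0.5 in every replicate. The
unpaired 1-SE variant (using the SE of the MSE itself) is too blunt at this
validation-set size: it swallows genuine 5-percent MSE improvements and
drops strong signals, which is why the paired form is used.

A component survives Step 1 only if selected in at least `ceil(m/2)` of the
m imputed copies (10 of 20 at the default m = 20).

**Step 2 — pooled, attrition-weighted backward elimination.** Weighted
least squares of the standardized scale on the survivors plus demographics
is fitted in every copy and pooled by the combining rules below. Components
are removed one at a time, deterministically: first any component whose
pooled coefficient has the wrong sign (positive components should raise fl
and ls and lower pd, wr, sa), worst p first; once all signs agree, the
component with the largest pooled p above 0.25; refit after each removal
until the survivors are clean. The wrong-sign-before-large-p priority is
this package's choice — both rules are part of the procedure but their
order is not prescribed anywhere — and makes the elimination path
deterministic given the imputation set.

Note a deliberate asymmetry carried over from the published procedure: the
LASSO stage ignores attrition weights, the final regressions use them.

## Multiple imputation

Missing component, scale-wave and outcome cells are completed m = 20 times
by chained equations, 10 burn-in cycles per copy. Binary variables are
imputed by logistic draws, continuous ones by Bayesian normal-linear draws
(peak earnings on the log scale, back-transformed, floored at 0 and rounded
to dollars); coefficient vectors are perturbed by a draw from their
estimated posterior before each prediction, so the imputations are proper.
Every conditional model uses demographics, log attrition weight and the
current values of all other imputable variables as predictors, adult
outcomes included (congeniality with the analysis models). Demographics and
attrition weights must be fully observed.

Estimates are pooled with the standard combining rules: pooled estimate =
mean across copies, total variance = within + (1 + 1/m) x between, and a
t reference distribution with Barnard–Rubin small-sample degrees of freedom
when the complete-data degrees of freedom are available (the large-sample
formula otherwise). PCA under imputation averages the per-copy correlation
matrices and eigendecomposes once — symmetric in the copies and
deterministic.

## Predictive validity

For binary young-adult outcomes (ever fair/poor health, ever depressed),
an attrition-weighted logistic regression of the outcome on the
standardized index score plus demographics yields the average marginal
effect of a one-SD increase: the weighted sample mean of
`p(score + 1) − p(score)`, variance by the delta method, pooled over
imputations. (The finite-difference form is the default; scores are
standardized so +1 unit is +1 SD.) For peak earnings, a weighted Poisson
regression with a robust sandwich covariance and controls for observed
years aged 20–29, enrollment at the peak year and household position yields
the percent change `100 (exp(beta) − 1)`.

Partial R² is the increment in explained variance over the controls-only
model: Efron's squared-residual pseudo-R² for binary outcomes and the
squared-correlation R² for earnings — both coincide with ordinary R² in the
linear case, so the full-minus-base subtraction is well defined.

Two indices fitted on the same sample (e.g. the hedonically weighted index
vs the equal-weight count of positives) are compared by stacking their
estimating equations: the joint sandwich covariance of both coefficient
vectors, with the cross block assembled from per-observation score
contributions, propagates through the difference in marginal effects. A
seeded paired bootstrap is available as a fallback. Under the null the
stacked test's p-values are uniform (verified by simulation in the test
suite). Complex-survey variance (strata/PSUs) is deliberately out of
scope — attrition weights only.

## The synthetic cohort generator

No public release of the source panel exists, so the generator provides
cohorts with the same statistical structure and known ground truth. Each
child carries a latent thriving factor `u ~ N(0,1)`. Components are
Bernoulli in positive framing, optionally age-tilted on the logit scale
(the hook that makes missingness informative). Scale j's wave-w value is

    center_j + spread_j * ( loading_j * u + sum_z effect[j,z] * comp_z + eps_jw )

with per-wave noise; the life-satisfaction item is rounded to integers and
clipped to 1–5. Adult outcomes depend on an overall thriving score (latent
factor plus the components' well-being contributions, the latter scalable
via `component_scale`); earnings are log-normal, rounded, floored at 0.
Missingness is missing-at-random: a logistic row propensity in age, sex and
log attrition weight (all never missing), intercept calibrated so the
expected share of rows with at least one missing cell hits the target
(default 40%).

Because components are independent of `u` given age, the regression
coefficient of a standardized scale on a component identifies
`effect[j,z] / sd_j`, and the weights the pipeline should recover are
available in closed form (`true_weights`), including the wave-averaging and
discretization contributions to `sd_j` (rounding adds `(1/spread)^2 / 12`
per wave to the noise variance; clipping of the 1–5 item is ignored, which
is accurate while clipping stays rare).

Two presets are shipped. `psid_like_config` mirrors published descriptive
statistics of a US child panel: 13 individual and 6 contextual components
at realistic positive-framing prevalences (e.g. food secure 86.7%, on-time
graduation 80.0%), scale centers/spreads matching the published means and
SDs, a shared latent loading of 0.63 chosen so the first eigenvalue of the
scale correlation matrix sits near 2.6 of 5 (roughly half the variance, as
in the published PCA), effect sizes at the magnitudes of the published
regressions, and 40% row missingness. `recovery_preset` is the
parameter-recovery benchmark: 11 signal components whose effect vectors
share one direction — making the true normalized weights exactly
proportional to the per-component magnitudes (0.35 down to 0.10) — plus 5
null components, complete data. The smallest magnitude is set so every true
per-scale coefficient sits several standard errors above zero at the
default n = 20,000; a recovery benchmark whose weakest signals are at the
noise floor could not distinguish estimation failure from statistical
impossibility.

### What the synthetic data does not show

The generator draws components independently (given age) and scales with a
single common factor; real panel components are mutually correlated through
many pathways, scales have heavier tails and floor effects, and attrition
is informative in ways the loose log-linear weight model does not capture.
Passing the recovery tests therefore demonstrates the correctness of the
estimation machinery under its own assumptions, not the field validity of
the index. The published weights themselves are reproduced only through the
golden check (below), which uses the published regression outputs, not
microdata.

## Known limitations and numerical notes

- **Null components can survive selection.** The backward-elimination gate
  deliberately admits any component with expected sign and pooled p < 0.25.
  On a single complete-data cohort, a null whose realized |t| is large with
  the expected sign is indistinguishable from a weak true component, and
  with 5 nulls x 5 equations per run such cells are common enough that
  roughly a quarter to a third of recovery runs end with at least one null
  carrying a small (< 0.01) weight. The majority retention rule cannot
  remove them because all copies of a complete-data cohort are identical —
  the luck is in the data, not the splits. Their weight impact is well
  inside the recovery tolerance.
- Degenerate inputs are errors, not silences: constant scales, rank-
  deficient scale correlation matrices, all-zero coefficient matrices,
  outcomes without variation, unimputable (never-observed) variables and
  mismatched component columns all raise with the offending name.
- An all-components-eliminated selection outcome for one scale is valid
  (empty equation, zero coefficients) and is flagged in the elimination
  trace rather than raised.
- Ties in the elimination step are broken by the largest pooled p; the
  loading vector's sign is fixed by the flourishing entry; standardization
  uses the n−1 denominator throughout.
- Reproducibility: every stochastic stage draws from named substreams of
  one master seed; identical configuration yields byte-identical artifacts.

## Problem sizes used in the shipped checks

The test suite exercises the pipeline at the scales the statistical claims
require and no larger: the golden reconstruction is exact arithmetic on the
published 11 x 5 inputs; selection operating characteristics use n = 2,000
with 50 replicates; end-to-end recovery uses n = 20,000 cohorts over 20
seeds with m = 20; comparison-test calibration uses 200 null replicates of
n = 800. Unit tests run on cohorts of 500–8,000.
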