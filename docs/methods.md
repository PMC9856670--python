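# Methods

This note records the statistical model, the estimators, the numerical
choices and the design decisions behind `pshscreen`, in the spirit of a
package vignette. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Competing-risks data and the Fine–Gray model

Each subject contributes a follow-up time Y = min(T, C), a cause code
ε ∈ {0, 1, 2, …} (0 = censored, 1 = event of interest, ≥ 2 = competing
causes; ties between failure and censoring resolve to failure), a
feature vector X ∈ ℝᵖ subject to screening, and controls Z ∈ ℝᵖ⁰ that
are always adjusted for. Cause codes above 2 are accepted and pooled
with cause 2 for weighting purposes.

The cause-1 cumulative incidence F₁(t; x, z) = Pr(T ≤ t, ε = 1 | x, z)
is modelled through its subdistribution hazard, assumed proportional:
λ₁(t; x, z) = λ₁₀(t) exp(βᵀx + γᵀz). The defining feature of the
subdistribution risk set is that subjects who failed from a competing
cause *remain at risk* for cause 1; censored subjects leave it, and the
information loss is corrected by inverse-censoring weights

    w_i(t) = I(C_i ≥ Y_i ∧ t) · Ĝ(t) / Ĝ(Y_i ∧ t),

with Ĝ the Kaplan–Meier estimate of the censoring survival
G(t) = Pr(C ≥ t). Two conventions are fixed once and used everywhere:

* **Evaluation side.** Because G is a "≥" probability, Ĝ is evaluated
  left-continuously: the drop caused by a censoring at t takes effect
  strictly after t. This makes Ĝ(Y_i) well defined and positive for
  every observed subject and equals the usual "Ĝ(t−)" of
  right-continuous notation.
* **Ties.** At tied failure/censoring times, failures precede
  censorings: a subject failing at t still counts as at risk for
  censoring at t. At tied cause-1 event times the Breslow
  approximation (shared denominator) is used, matching the displayed
  form of the weighted partial likelihood.

The indicator I(C_i ≥ Y_i ∧ t) is resolved from observables: it is 1
whenever t ≤ Y_i, and for t > Y_i it is 1 iff the subject was observed
to fail (ε ≠ 0).

## 2. Estimation

Coefficients maximise the weighted log partial likelihood
l_n(β, γ) = Σ_{cause-1 events} [η_i − log Σ_j w_j(Y_i) R_j(Y_i) e^{η_j}]
by Newton–Raphson with analytic score and Hessian, step-halving on any
non-increase, zero initialisation, and convergence when the relative
log-likelihood change falls below 1e−9 (cap: 100 iterations). The
weights are computed once from Ĝ and frozen during optimisation (they do
not involve β, γ). Risk-set sums are computed with a max-shift of the
linear predictor to prevent overflow. A fit whose standardised
coefficient magnitude exceeds 30 is flagged unconverged (monotone
likelihood / separation); a singular information matrix raises an error
naming the collinear columns. The fitted object carries the Breslow
cumulative baseline hazard (jumps d(t)/Σ_j w_j(t)R_j(t)e^{η̂_j} at
cause-1 event times) and predicts the CIF as
F̂₁(t|x,z) = 1 − exp(−Ĥ₁₀(t) e^{β̂ᵀx+γ̂ᵀz}).

Coefficient covariance is reported as the inverse of the negative
Hessian and labelled **naive** throughout: the full Fine–Gray sandwich
that accounts for the estimated Ĝ requires influence-function terms and
is out of scope. Wald intervals and p-values derived from it inherit
the label.

An identifiability guard refuses fits with at least as many coefficients
as cause-1 events.

## 3. Screening (PSH-CSIS)

Each feature j is scored by û_j = max_{β_j, γ} l_n(β_j, γ) from the
two-stage model (X_j, Z); the top d features are recruited. Details:

* The null fit max_γ l_n(0, γ) is computed once and its γ̂ warm-starts
  every per-feature Newton solve (large speedup, same maximiser).
  The precomputed risk-set weight matrix is likewise shared across all
  p fits, so screening p = 500 features at n = 200 takes well under a
  second.
* Features whose fit fails (constant column, separation,
  non-convergence) are **demoted**, not propagated: û_j is set to the
  null log-likelihood and flagged. Screening must be robust to a few
  degenerate columns among thousands.
* Ties in û_j break by ascending feature index, making the ranking
  deterministic. û_j is clamped from below at the null log-likelihood
  (a free parameter cannot lower the maximum; finite tolerance can
  leave ~1e−10 slack).
* Model-size rules: ⌊n/log n⌋ and its 2× and 3× multiples, and
  n − p₀ − 1 (the default).

## 4. Component-wise boosting with mandatory controls

Starting from β = 0 and γ at the controls-only maximum, each boosting
step computes, for every candidate feature at the current linear
predictor, the per-coordinate score U_j and curvature I_j, updates the
feature maximising the penalised score statistic U_j²/(I_j + λ) by
δ_j = U_j/(I_j + λ), then refreshes γ by one unpenalised Newton step
(halved if it would decrease the likelihood, so the training likelihood
is non-decreasing along the whole path). Defaults:

* λ = 9 × (number of cause-1 events), the likelihood-boosting
  convention giving per-step shrinkage ≈ 0.1 of the unpenalised Newton
  step; only the step count M is tuned, λ stays at the rule value.
* M is chosen in 0..max_steps (default 100) by K-fold (default 10)
  cross-validation, folds stratified by cause code, scored by the
  held-out fold's weighted partial log-likelihood with the fold's own
  Ĝ; the *first* maximiser is taken, preferring the sparser model.
  Fold draws that leave a fold without cause-1 events are re-drawn (up
  to 10 attempts). This simple held-out score was cross-checked against
  the Verweij–van Houwelingen full-minus-train form, which selected
  near-identical step counts on all designs exercised here.

A caveat the test suite documents explicitly: under pure-noise features
the cross-validated step count is *not* reliably zero. CV folds come
from a single dataset draw, so a feature spuriously correlated with the
outcome at the dataset level looks predictive in every fold; M* = 0 is
the modal choice and occurs far above chance, but only at roughly a
coin-flip rate. This is a property of argmax CV selection, not of the
implementation.

## 5. Evaluation

**IPCW Brier curve.** Err(t) = (1/n) Σ (N_i(t) − F̂₁(t|X_i,Z_i))² W_i(t)
with W_i(t) = I(Y_i ≤ t, ε_i ≠ 0)/Ĝ(Y_i) + I(Y_i > t)/Ĝ(t) and the
marginal Kaplan–Meier Ĝ (no covariate conditioning); the Ĝ terms are
divisors. Grid points where Ĝ = 0 are truncated with a warning.

**.632+ bootstrap.** Apparent error from the full fit; out-of-bag error
from B (default 100) subject-level resamples, each out-of-bag cohort
weighted by its own Ĝ; the no-information error scores every subject's
outcome against every subject's prediction; the blend uses the relative
overfitting R clamped to [0, 1] (R = 0 with a warning when the
no-information error does not exceed the apparent error). Refittable
model recipes are re-run per resample; in the pipeline, boosting recipes
reuse the step count tuned once on the full training cohort, keeping the
bootstrap tractable.

**Time-dependent ROC.** At horizon t, cases are cause-1 failures by t
(weight 1/Ĝ(Y_i)); controls are both event-free survivors (weight
1/Ĝ(t)) and competing-cause failures by t (weight 1/Ĝ(Y_i)) — the
latter are known to be permanently cause-1-free, consistent with the
CIF being the prediction target. AUC is the weighted concordance with
ties counted ½, which equals the trapezoidal area of the traced curve.

## 6. Nonparametric incidence and Gray's test

The Aalen–Johansen estimator accumulates Ŝ(s−)d_k(s)/n(s) per cause,
with Ŝ the all-cause Kaplan–Meier; at every event time the cause CIFs
and Ŝ add to exactly 1.

Gray's K-sample test (ρ = 0 only, the default of the standard software)
is implemented in its **IPCW formulation**: the group-level weighted
risk sets h_g(t) = Σ_{i∈g} w_i(t)R_i(t) built from the pooled censoring
Kaplan–Meier, which by the product-limit identity match the classical
retention of competing-cause subjects with factor (1 − F̂₁(t−))/Ŝ(t−).
The score is z_g = Σ_t [dN₁g(t) − h_g(t) dN₁(t)/h(t)]. Its covariance
is estimated from per-subject influence terms: the martingale residual
part plus a censoring-martingale correction for the estimated weights
(the perturbation of Ĝ propagated through w_i). The statistic
zᵀV⁻z (generalised inverse; the influence rows sum to zero exactly, so V
is singular by construction) is referred to χ² with K − 1 degrees of
freedom. This is a consistent variance in the same asymptotic family as
the classical one, not a port of its finite-sample formulas; the type-I
error simulation in the acceptance suite (n = 200, 2000 replicates) and
a cross-check against the independent R implementation (statistics
within ~10–15% on n = 200–400 fixtures) validate the calibration.

**Risk stratification.** The risk score is the linear combination of the
selected features with their fitted coefficients; the cutoff is the
training median (midpoint of central order statistics for even counts);
scores strictly above the cutoff are high-risk; the frozen cutoff is
applied unchanged to test subjects. A degenerate median (imbalanced
groups) warns rather than errors; identical training scores error.

## 7. Synthetic data generator

The simulator draws from the classical unit-exponential mixture design,
chosen because it makes the proportional-subdistribution assumption hold
*exactly*, giving a clean parameter-recovery oracle:
P(ε=1|v) = 1 − (1−π)^{e^{η₁}} and F₁(t; v) = 1 − [1 − π(1−e^{−t})]^{e^{η₁}}
(cause-1 times by inverse CDF), cause-2 times exponential with rate
e^{vᵀβ₂}, censoring independent Uniform(0, c). Features are standard
normal with AR(1) cross-column correlation ρ; controls default to one
standard normal plus one Bernoulli(½) indicator, echoing a clinical mix
of one continuous and one binary covariate.

Canonical fixtures (fixed seeds, regenerated programmatically — nothing
is stored on disk): `tiny` (n = 8, hand-checkable), `screening`
(n = 200, p = 500, four active features at |β| = 0.8 placed 100 columns
apart so the AR(1) correlation between actives is negligible, ρ = 0.25),
`boosting` (n = 400, p = 50, one dominant feature at β = 1.5),
`evaluation` (n = 300, ~30% censoring). The uniform-censoring upper
ends were calibrated once at construction to the stated censoring
fractions (3.0, 4.0, 2.4 and 3.1 time units for the screening, boosting,
evaluation and single-feature recovery designs, giving ≈27%, ≈20%, ≈30%
and ≈30% censored) and are fixed constants thereafter.

What the generator does *not* emulate: microarray intensity
distributions, heavy-tailed or batch-structured noise, feature
correlation beyond AR(1), covariate-dependent censoring, or
non-proportional subdistribution effects. Tests passing on these
fixtures therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to their violation.

## 8. Cohort splitting

Train/test splitting is stratified random sampling on the cross of the
cause code with quantile bins (default 4) of the first control column,
with largest-remainder apportionment so each stratum contributes its
floor or ceiling share and the overall train size is exactly
round(n·ratio). This replaces support-points-based splitting with a
testable mechanism that achieves the same goal (cohorts with similar
event composition and clinical profile).

## 9. Problem sizes and benchmarks

The Monte-Carlo checks run at deliberately moderate sizes chosen to give
stable rates on a single CPU: coefficient recovery at n = 1000 × 200
replicates; sure screening at n = 200, p = 500 × 100 replicates;
Gray-test calibration at n = 200 × 2000 replicates; and the
benchmark-ordering study (screen + boost vs the covariate-free
Aalen–Johansen null) at n = 300, p = 60 with a 4:1 split, d = ⌊n/log n⌋,
5-fold CV over ≤ 30 boosting steps, × 50 replicates, compared by
grid-averaged IPCW Brier error on the held-out fifth.

## 10. Known limitations

* Naive (model-based) variance for PSH coefficients; no
  influence-function sandwich.
* No time-varying coefficients, stratified baselines, left truncation,
  or covariate-dependent censoring models.
* Lasso-penalised PSH selection is not implemented; the boosting layer
  exposes the selector interface where it would slot in.
* Gray's test implements ρ = 0 weighting only.
* The `.632+` out-of-bag estimate requires every grid point to be
  usable in at least one resample; very heavy censoring near the grid
  end can void it.
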