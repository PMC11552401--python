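# Methods

## The model and its assumptions

`fusionaudit` fits covariance-structure models by normal-theory maximum
likelihood. Every model is expressed in an all-latent form: observed variable
x loads with a fixed unit loading on a true-score latent ts_x, the
measurement-error variance of x is *fixed* at (error% / 100) × Var(x), and all
causal structure runs among latents. The implied covariance is

    Σ(θ) = Λ (I − B)⁻¹ Ψ (I − B)⁻ᵀ Λᵀ + Θ,

with Λ the loading matrix, B the (acyclic) latent-to-latent effect matrix, Ψ
the exogenous/disturbance (co)variances and Θ the measurement-error
(co)variances. The discrepancy minimised is

    F(S, Σ) = ln|Σ| + tr(S Σ⁻¹) − ln|S| − p,

and the test statistic is χ² = (N − 1)·F_min with df = p(p+1)/2 − q free
parameters. The (N − 1) scaling is the classic LISREL convention; an
N-scaling switch exists on `chi_square_stat`/`fit_ml` (`chi2_scale="n"`).
The normality assumption enters only through the discrepancy; means are
carried as metadata and never modeled — all fit statistics are
covariance-based.

A composite scale is a latent receiving *fixed* paths (the scoring weights)
from its items' true scores, with disturbance variance fixed at zero. Its
model value is therefore numerically identical to the arithmetic scale score
computed from true scores. The data-side scale-score variable (when present,
or appended by `augment_covariance_with_scores`) is the weighted sum of the
*observed* items and so contains weighted item error; composites are built on
true scores deliberately, because the percent-error adjustment is the point
of the all-latent layer. A sensitivity analysis with raw-item composites can
be had by setting all item error percentages to zero.

## Estimation and numerical choices

* **Optimizer.** L-BFGS (analytic gradient, at most 150 iterations) followed
  by Fisher scoring with step-halving, using the expected information
  I_jk = tr(Σ⁻¹ ∂Σ_j Σ⁻¹ ∂Σ_k) as the Hessian. Scoring converges
  quadratically near the optimum, which is what makes population-covariance
  fits reach F < 1e−12. Convergence requires max|∂F| < 1e−6 and a function
  change below 1e−10.
* **Starting values.** Loadings at their fixed values (free ones at 1), free
  structural paths at 0, free variances at half the corresponding sample
  variance, free covariances at 0.
* **Non-PD excursions.** If a step leaves the positive-definite region the
  objective returns a smooth eigenvalue-penalty barrier with its gradient, so
  line searches back off rather than crash.
* **Admissibility.** Negative variance estimates are flagged
  (`FitResult.admissible = False`), never constrained away: silently forcing
  admissibility would mask exactly the misspecification the audit looks for.
* **Standard errors.** acov(θ̂) = (2/(N−1)) I⁻¹ at the solution; a singular
  information matrix raises an identification error naming the null-space
  parameters. The |estimate|/SE bands (≥2, ≥3) drive the table marks.
* **Standardization.** Coefficients are rescaled by model-implied latent
  SDs; free exogenous covariances are reported as correlations. Total
  effects are (I − B_std)⁻¹ − I.
* **Printing.** χ² and p to 2 dp in human output, full precision in machine
  output.

## Modification indices and the forward search

The search instrument is the univariate score (Lagrange-multiplier) test:
for a fixed-at-zero path with discrepancy gradient g and expected-information
curvature h partialled on the free parameters,

    MI = (N − 1) g² / (2h),    EPC = −g / h.

`forward_search` frees the largest-MI candidate, refits (all freed effects
re-estimated jointly each step), and records the trail. Defaults: candidate
threshold χ²₁(.01) = 6.64, stop when the model p-value reaches .05 or no
candidate clears the threshold; ties break by candidate order. All
thresholds are arguments; the trail is always logged. The item-only audit
stage starts from the effects the expanded scale-and-item model required and
searches the remaining candidates.

## The audit sequence

`run_audit` follows the method's development order: basic fusion model →
forward search → expanded model; then the scale-only model (appending
arithmetic scale-score variables to the covariance matrix if absent) and the
item-only model with its own search. The verdict reports the basic-fusion
χ² decision, the demanded bypassing effects, a per-item profile from the
item-only model (none / partial / full / sign_reversal, the expected sign
being the weight-weighted sign of the scale-only scale effects), and the
attenuation of each scale effect between the scale-only and expanded models.

## The synthetic test bed

Two generating scenarios ship with the package; both specify a *population*
covariance implied by a fusion structure, from which sample covariances are
drawn (exact Wishart by default, or explicit Gaussian observations).

* `care_aide_scenario` emulates a care-aide work-life survey at realistic
  scale: eight health-survey items with 5% assigned error and observed
  variances on the scale of real survey data (e.g. 49.84 for the health
  rating, 52.64 for the work-limitation item), two composite scales built
  from all eight items, four chained work-life outcomes, and seven controls
  carrying seventeen control paths. Eleven control paths follow directly
  from the substantive rationale (staffing, team support and disruptive
  resident actions feeding the tired/rushed/burnout/looking-forward chain);
  the remaining six (two each for sex, age and second-language status) were
  placed so that the four model variants have the canonical degrees of
  freedom (11 scale-only, 35 basic fusion, 32 candidate item effects) —
  the df arithmetic is consistent only with seventeen. The scoring weights
  are synthetic stand-ins (the real instrument's weights are
  license-restricted): every item contributes to both scales, one scale
  dominated by the physical items, the other by the emotional ones.
  Standardized structural effects sit in the weak-but-significant 0.05–0.25
  band.
* `compact_scenario` is a one-scale layout (four items, two downstream
  variables, two controls) used for replicate-heavy simulation so that
  500-replicate calibrations finish in tens of seconds; the type-I and power
  properties it checks do not depend on layout size.

An invalid-fusion scenario adds direct item → downstream paths of stated
standardized magnitude; `recovery_experiment` reports per-parameter
bias/RMSE, the basic-fusion rejection rate, and (optionally) what the forward
search selects. Seeding: one master seed expands to per-replicate seeds via
`numpy.random.SeedSequence.spawn`, so a single integer reproduces every
replicate.

What the generator does *not* emulate: item responses are continuous
Gaussian, not the ordinal categories of real survey items; there are no
missing data; and the controls are only weakly correlated by construction.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under its own assumptions, not the behavior of the method under
coarse ordinal measurement.

## Known limitations

* ML only — no GLS/WLS/robust estimators, no polychoric input, no mean or
  multi-group structures, and no fit indices beyond χ²/df/p (the audit
  argues from the χ² test deliberately).
* The forward search is univariate and greedy; jointly re-estimated but not
  a joint multivariate LM test. Different covariance matrices can produce
  different trails when MIs are nearly tied.
* Structural graphs must be acyclic.
* Auditing the original care-aide data requires the study's archived
  covariance matrix and licensed scoring weights, supplied by the user at
  run time (`data/appendix_a/`); the package ships only synthetic
  stand-ins, labelled as such.
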