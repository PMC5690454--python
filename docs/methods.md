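# Methods

## Model and procedure

The pipeline estimates chronological age-at-death from an ordinal skeletal
indicator in four stages.

**1. Gompertz prior.**  Adult mortality is modeled by a Gompertz hazard with
the clock started at the adult floor: h(t) = α exp(βt) with t = a − 18 years.
The survivor function S(t) = exp(−(α/β)(e^{βt} − 1)) and density
f(a) = h(a)S(a) follow in closed form.  The model assumes closed death
records (every individual's age-at-death is observed; no censoring or
right-truncation) and ignores the pre-adult hazard entirely — both reasonable
for cemetery and skeletal-collection data restricted to adults.  Fitting is
maximum likelihood over (ln α, ln β) with a Nelder–Mead simplex; the log
parameterization enforces positivity and copes with the flat ridge in the
(α, β) likelihood that correlated Gompertz parameters produce.  The simplex
is seeded by regressing the log of a crude 5-year-binned empirical hazard on
bin midpoints, which the Gompertz form makes log-linear.  Convergence
tolerance is 1e-10 on the per-observation negative log-likelihood; failures
raise an error carrying the optimizer diagnostics.  Ages are used as exact
reals with no half-year correction.  Individual-level ages are assumed;
grouped-data likelihoods are out of scope.

**2. Transition analysis.**  Phase membership given age is a cumulative
probit on natural log age with ordered thresholds τ_1 < … < τ_{K−1} and a
spread σ shared across transitions.  The shared-σ ("proportional") form is
the standard one for this model family; with 8 phases and a few hundred to a
few thousand observations, per-transition spreads are weakly identified, so
the shared spread is the default and only form.  exp(τ_j) is the median age
of the j → j+1 transition.  The MLE optimizes τ_1, the log-gaps between
successive thresholds, and ln σ — all unconstrained — so ordering and
positivity hold by construction.  Seeds: τ_j at the log-midpoint between mean
ages of adjacent observed phases (linearly interpolated across unobserved
phases), σ at the pooled within-phase SD of log age.  Phases with no
observations are kept in the model at fixed K (ranges must be reported for
every phase of the scoring system); the fit records a warning because their
boundaries are weakly identified.  Near-zero fitted σ or collapsed thresholds
(complete separation) also produce a warning rather than an error.

**3. Posterior and HPD ranges.**  The posterior Pr(a | c_j) ∝ Pr(c_j | a)f(a)
is evaluated on a uniform grid, by default 0.01 years from 18 to 130 — the
ceiling sits safely above any age the reference priors give non-negligible
mass, and numerator and denominator use the same trapezoid rule, making
normalization exact up to quadrature error (checked at 1e-6).  Age ranges are
true highest-posterior-density regions, not equal-tailed intervals; the two
differ for the skewed posteriors truncated at 18.  The waterline threshold
c* is found by 60 bisection steps on [0, max density]; all grid points at or
above the final threshold are included, which can only push the achieved mass
above the nominal coverage, and the achieved mass is reported alongside.
Posteriors maximal at the age floor keep the floor as the lower bound — no
interior-mode assumption is made, so the youngest phase's range starts at
exactly 18.  A disconnected super-level set (possible for multimodal
densities) is reported as its bounding interval with a `disconnected` flag.
Endpoints are rounded to 2 decimals for display; classification and all
internal computations use the unrounded values.

**4. Coverage evaluation.**  A hold-out individual is a success iff their
documented age lies inside their phase's range, endpoints inclusive (HPD
regions are closed sets on the grid).  The pooled test treats every hold-out
individual as one Bernoulli trial at the nominal coverage.  The headline
p-value is the exact lower tail P(X ≤ successes | n, nominal) — the question
being whether the ranges cover *fewer* individuals than designed — with the
exact two-sided value reported alongside for transparency, since published
analyses do not always state their sidedness.  No multiple-testing correction
is applied across priors or phases.

## Parameters that matter

| Parameter | Units | Default | Why |
|---|---|---|---|
| `age_offset` | years | 18 | adult-only samples; hazard clock start |
| `grid_step` | years | 0.01 | endpoint resolution ≈ the 2-dp display precision |
| `age_max` | years | 130 | upper bounds near 114 occur with flat national priors |
| `coverage` | probability | 0.90 | the conventional reporting level for these ranges |
| `n_phases` | count | 8 | the common auricular-surface scoring system |
| fit tolerance | — | 1e-10 | α is O(1e-4); loose tolerances bias the ridge |

## Synthetic data

`simulate_ages` draws ages by inverse-CDF sampling of the left-shifted
Gompertz (t = ln(1 − (β/α) ln U)/β); `simulate_phases` draws phases from the
probit categorical at each age; `make_scenario` splits one seed into
independent streams (prior ages, hold-out ages, hold-out phases) so adding an
operation never perturbs another's draws, and records the generating truth in
a sidecar.  Defaults emulate the study design the pipeline targets: a
prior-fitting sample of 1022 (the size of the donated-collection reference
sample), a hold-out of 373 (the size at which published pooled binomial
tests were run), and a documented 8-phase transition model with median
transition ages 30, 38, 45, 55, 65, 75, 85 years and σ = 0.25 — invented
values, chosen so the phase-specific age spans widen with phase as real
auricular-surface data do.  No published transition parameter set for this
indicator is bundled; externally obtained parameters can be supplied as a
JSON file, and the Bayes stage never depends on the fitting stage.

What the generator does *not* emulate: age heaping and rounding in documented
ages, inter-observer scoring error, the conflicting-trait scoring rules real
osteologists apply, kinship or selection bias in who enters a cemetery or
collection, and any secular trend.  Passing calibration tests therefore show
the chain is self-consistent — ranges built from a correctly specified model
cover 90% of individuals drawn from that model — not that real skeletal
samples achieve nominal coverage; published evaluations on documented
collections find realized coverage below nominal, and the misspecification
machinery here (generating hold-outs from a flatter mortality model than the
prior) reproduces that direction.

## Numerical choices and degenerate inputs

- Trapezoid quadrature throughout; numerator and denominator of the posterior
  share a grid, so the normalization check at 1e-6 is a discretization test.
- The brute-force HPD cross-check in the tests uses trapezoid point masses
  (half-weight endpoints) so both routes integrate the same measure; they
  agree within one grid step.
- Probabilities are floored at 1e-300 inside the transition log-likelihood to
  keep impossible (age, phase) pairs from producing −inf during optimization.
- A phase whose likelihood × prior is identically zero on the grid raises a
  degenerate-posterior error naming the phase.
- All-identical age samples are rejected before fitting; empty hold-out files
  fail before any artifact is written.
- Ages exactly 18 are valid everywhere (ln 18 is finite; the floor is part of
  the support).

## Problem sizes

The test suite and acceptance script run at the scales the method is used
at: parameter-recovery fits at n = 5000 (Gompertz, 20 seeds per reference
prior) and n = 2000 (transition), calibration at 50 hold-out replicates of
373, type-I calibration at 200 replicates.  The full suite completes in well
under a minute on one CPU.

## Known limitations

- Single ordinal indicator only; no multi-indicator joint models.
- No Gompertz–Makeham or Siler hazards, no censoring or truncation beyond
  the fixed left shift, no grouped-age likelihood.
- HPD extraction assumes the grid resolves the density; pathological
  near-plateau densities could make the reported interval sensitive to the
  bisection tie rule (the achieved mass is always reported so this is
  visible).
- The exact binomial test's sidedness convention is a reporting choice;
  both tails are printed, but only the lower tail drives the headline
  p-value.
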