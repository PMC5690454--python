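# bayesage

Bayesian age-at-death estimation from ordinal skeletal indicators, for
biological anthropologists, bioarchaeologists, and forensic practitioners who
need age ranges with known coverage rather than the fixed brackets of
traditional scoring methods.

## The model

Skeletal indicators such as the auricular surface of the ilium are scored
into ordinal phases (the common 8-phase system); higher phases indicate older
individuals, but a phase alone brackets chronological age poorly.  This
package combines two components via Bayes' theorem:

**Informative prior.**  Adult mortality in a reference sample follows a
left-shifted Gompertz hazard

    h(t) = α exp(βt),   t = a − 18,

with baseline mortality α and senescence rate β, fitted to death records by
maximum likelihood.  Four published (α, β) pairs for American male samples —
a donated skeletal collection, a local cemetery, the surrounding county, and
the national population — ship as `REFERENCE_PRIORS`.

**Transition analysis.**  The probability of observing phase *j* at age *a*
is a cumulative probit on log age:

    Pr(c_j | a) = Φ((τ_j − ln a)/σ) − Φ((τ_{j−1} − ln a)/σ),

with ordered thresholds τ (so exp(τ_j) is the median age of the j → j+1
transition) and a shared spread σ, fitted by maximum likelihood to
(documented age, phase) observations.

The posterior density of age given a phase,

    Pr(a | c_j) = Pr(c_j | a) f(a) / ∫ Pr(c_j | x) f(x) dx,

is computed by trapezoid quadrature on a fine age grid, and each phase is
summarized by its highest-posterior-density range (HPDR): the shortest
interval holding a stated coverage, e.g. 90%.  Realized coverage on a
hold-out sample is tested against the nominal level with exact cumulative
binomial tests.  A synthetic-data generator (Gompertz ages by inverse-CDF
sampling, probit phase assignment) makes the whole chain testable end to end.

## Worked example

Fit a prior on a synthetic sample of 1022 deaths, build 90% HPD ranges for
all 8 phases, and evaluate coverage on an independent 373-person hold-out:

```python
from bayesage import (coverage_report, fit_gompertz, hpdr_frame, hpdr_table,
                      make_scenario)
from bayesage.simulate import DEFAULT_TRANSITION, ScenarioConfig

scenario = make_scenario(ScenarioConfig(prior_label="donated", n_prior=1022,
                                        n_holdout=373, seed=1))
fit = fit_gompertz(scenario.prior_sample)
print(f"fitted prior: alpha={fit.params.alpha:.6g} beta={fit.params.beta:.6g}")
ranges = hpdr_table(fit.params, DEFAULT_TRANSITION, 0.90)
print(hpdr_frame(ranges).to_string(index=False))
report = coverage_report(scenario.holdout, ranges, 0.90)
print(report.summary_frame("donated").to_string(index=False))
```

```
fitted prior: alpha=0.000466665 beta=0.0755567
 phase  lower  upper  coverage  achieved_mass  disconnected
     1  18.00  45.28       0.9       0.900105         False
     2  25.92  65.79       0.9       0.900060         False
     3  33.79  77.97       0.9       0.900038         False
     4  42.65  87.59       0.9       0.900038         False
     5  51.41  93.77       0.9       0.900051         False
     6  58.08  97.46       0.9       0.900091         False
     7  63.12  99.89       0.9       0.900069         False
     8  70.54 104.00       0.9       0.900009         False
 sample  coverage  successes  failures  p_value_lower  p_value_two_sided  p_success
donated       0.9        327        46        0.08148             0.1416   0.8767
```

Phase I starts exactly at the adult floor of 18 years, ranges widen with
phase (skeletal aging grows more variable), and 327 of 373 hold-out
individuals (87.7%) fall inside their phase's range — consistent with the
nominal 90% at this sample size (lower-tail binomial p = 0.08).

The same workflow is available from the shell:

```sh
bayesage simulate --n-prior 1022 --n-holdout 373 --seed 1 --out-dir sim
bayesage fit-transition sim/holdout.csv --out trans.json
bayesage hpdr --prior donated --transition trans.json --out ranges.csv
bayesage run-all --synthetic --seed 1 --out-dir run
```

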