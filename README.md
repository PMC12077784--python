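# previnc

**Maximum-likelihood estimation of age-specific incidence rates of chronic
conditions from aggregated cross-sectional prevalence data.**

Age-specific incidence rates are usually estimated from longitudinal
cohorts, which are slow, expensive and prone to loss to follow-up.  For a
chronic (irreversible) condition, however, the illness-death model
(Healthy → Diseased → Dead, plus Healthy → Dead) ties the age profile of
*prevalence* to the incidence rate *i(a)* and the mortality rates of the
non-diseased (*m₀*) and diseased (*m₁*) through the partial differential
equation

```
(∂t + ∂a) p = (1 − p) [ i − p (m₁ − m₀) ]
```

so a single cross-sectional survey — counts *cₖ* of affected persons among
*nₖ* observed per 5-year age group — carries information about incidence.
`previnc` turns that observation into a full likelihood-based estimator:
the counts are modelled as `cₖ ~ Binomial(nₖ, pₖ)` with `pₖ` the ODE
solution at the group midpoint, the likelihood is maximized by BFGS, and
confidence intervals come from the inverse observed Fisher information
(Wald) and the delta method — no bootstrap resampling.

Three mortality situations are covered, each a model class:

| class | mortality input | prevalence solution |
|---|---|---|
| `NonDifferentialIncidenceModel` | none (m₁ = m₀) | closed form |
| `DifferentialMortalityIncidenceModel` | m₁ and all-cause m | integrating factor + quadrature |
| `PrevalenceSurfaceModel` | all-cause m and rate ratio R = m₁/m₀ | logistic surface `p(t,a) = expit(β₀+β₁(t−t₀)+β₂a+β₃a²)`, incidence by the plug-in formula `i = p·∂f + m·p(R−1)/(1+p(R−1))` |

Supporting modules convert abridged (5-year) life tables into Gompertz
mortality rates `exp(b₀ + b₁a)` (`previnc.lifetable`), forward-simulate
synthetic prevalence tables for recovery and coverage studies
(`previnc.simulate`), and expose everything as a CLI (`previnc`).

Two classic data sets ship with the package: breathlessness in British coal
miners (with paired England & Wales life tables) and type-2 diabetes in
German women, 2009–2010.

## Worked example

```python
import numpy as np
from previnc import NonDifferentialIncidenceModel, load_coalminers_prevalence

table = load_coalminers_prevalence()      # 9 age groups, 20-64 years
model = NonDifferentialIncidenceModel(table, a0=20.0, p0=0.0)
results = model.fit()
print(results.summary())
```

```
NonDifferentialIncidenceModel results
  log-likelihood kernel: -5994.1270
  converged: True   function evals: 195

     param     estimate    std err           [95% conf int]
    gamma0      -7.8234     0.1202       -8.059     -7.5877
    gamma1      0.07558   0.002823     0.070047    0.081113
```

The fitted incidence rate is `i(a) = exp(−7.823 + 0.0756·a)` per
person-year: about 0.4% of healthy 30-year-old miners develop
breathlessness each year, rising roughly e-fold every 13 years.  The
age-specific curve with a delta-method confidence band:

```python
print(results.incidence(np.array([30.0, 45.0, 60.0])))
```

```
 age  incidence       se  ci_lower  ci_upper
30.0   0.003864 0.000153  0.003577  0.004175
45.0   0.012007 0.000266  0.011498  0.012539
60.0   0.037308 0.002045  0.033508  0.041540
```

With mortality information the same table yields the differential-mortality
estimate (`DifferentialMortalityIncidenceModel(table, m1=..., m=...)`,
rates fitted from the packaged life table via
`gompertz_from_lifetable`), and the diabetes data give an age-incidence
curve from two years of prevalence by the plug-in route
(`PrevalenceSurfaceModel`).  The same analyses from the shell:

```sh
previnc fit-nondiff  --input src/previnc/datasets/coalminers_prevalence.csv --out-json fit.json
previnc lifetable    --input src/previnc/datasets/coalminers_lifetable.csv
previnc fit-diff-mr  --input src/previnc/datasets/diabetes_prevalence.csv --m="-11.35,0.1061"
```

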