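# Methods

## The illness-death model and its prevalence equations

For a chronic, irreversible condition the population at every age consists
of Healthy, Diseased and Dead, with transition rates *i(a)* (incidence),
*m₀(a)* (mortality of the non-diseased) and *m₁(a)* (mortality of the
diseased), all per person-year.  Writing *p(t, a)* for the prevalence among
those alive, the model implies

    (∂t + ∂a) p = (1 − p) [ i − p (m₁ − m₀) ],

and the all-cause mortality is the prevalence-weighted mixture
*m = (1−p) m₀ + p m₁ = m₀ [1 + p(R−1)]* with rate ratio *R = m₁/m₀*.
All estimators here assume the prevalence depends on age only (or on age
and a short calendar-year window), turning the PDE into an ODE in age.
Three forms of mortality knowledge give three estimable models:

1. **Non-differential** (*m₁ = m₀*): `p′ = (1 − p) i`, with closed-form
   solution `p(a) = 1 − (1 − p₀) exp(−∫ᵃ₀ i)`.  For Gompertz incidence
   `i(a) = exp(γ₀ + γ₁ a)` the cumulative hazard is itself closed-form.
2. **Diseased + general mortality known**: substituting the mixture
   identity gives `p′ = i − p (i + m₁ − m)`, solved with the integrating
   factor `exp(G)`, `G(a) = ∫ᵃ₀ (i + m₁ − m)`:
   `p(a) = e^{−G(a)} [ p₀ + ∫ᵃ₀ i(τ) e^{G(τ)} dτ ]`.
3. **General mortality + rate ratio known**: the PDE rearranges to the
   plug-in identity `i = p·∂f + m p (R−1)/(1 + p(R−1))` for any prevalence
   of the form `p = expit(f)`, where `∂f = (∂t + ∂a) f` is the drift of the
   log-odds along the life-course diagonal.  Here `f` is modelled as
   `β₀ + β₁ (t − t_ref) + β₂ a + β₃ a²`.

## Likelihood, optimization, and inference

Counts per (year, age-group) cell are independent binomial,
`c_k ~ Bin(n_k, p_k)`, with `p_k` the model prevalence at the group
midpoint.  Age groups use closed integer bounds, so "20 to 24" has midpoint
22.5.  The objective is the negative log-likelihood *kernel* — binomial
coefficients are constant in the parameters and omitted, so reported
log-likelihoods are kernels, comparable across fits on the same data only.

Optimization is BFGS (gradient tolerance 1e-8, up to three deterministic
jittered restarts).  The surface model additionally supplies its analytic
GLM score `Σ (n_k p_k − c_k) x_k`, which keeps BFGS stable despite the
intercept-vs-quadratic-term curvature imbalance.  Starting values: the
non-differential model starts from the descriptive OLS of observed
log-odds on midpoint age; the differential model starts from the
non-differential optimum; the surface model from (−2.3, 0.1, 0, −0.001).

The variance-covariance matrix is the inverse observed Fisher information:
a central-finite-difference Hessian of the kernel with per-parameter step
`max(1e-5, 1e-5·|θ|)` (parameters span four orders of magnitude).  When an
analytic score exists, the Hessian differences the score instead — the
information matrix of the quadratic-age surface is ill-conditioned
(condition number ~1e9) and double-differencing the objective loses ~1% of
a standard error there, verified against the closed-form logistic-GLM
information.  Parameter intervals are Wald; the z-quantile is computed,
not hard-coded.

Incidence-curve uncertainty: for the Gompertz scenarios the log incidence
is linear in (γ₀, γ₁), so the delta method on the log scale is exact and
exponentiating keeps the bounds positive.  For the plug-in estimator the
gradient of *i* with respect to (β₀…β₃) is taken by central differences
and propagated through the vcov; intervals are normal on the rate scale
(a very uncertain old-age estimate may have a negative lower bound), and a
negative *point* estimate is flagged and warned about, never clamped — it
diagnoses misspecified mortality inputs.  The plug-in curve is reported at
the reference year; all years enter the likelihood.

## Numerical choices

- **Quadrature** (model 2): adaptive Gauss–Kronrod on
  `∫ i(τ) e^{G(τ)−G(a)} dτ` with tolerances 1e-10; `G` uses the exact
  exponential closed form (with the linear limit at zero slope, computed
  via expm1 so slopes of any magnitude are safe).  When `G(a)` exceeds ~25
  the integrand collapses into a boundary layer at `τ = a`; geometric
  break points are passed to the quadrature, and in deep saturation
  (`G > 30`, p ≈ 1) the solver switches to the complement `q = 1 − p`,
  whose ODE `q′ = (m₁ − m) − q (i + m₁ − m)` has a small benign integrand.
  A fit fails hard only if the certified error cannot reach 1e-6, the
  level at which the solution is cross-checked against the Runge-Kutta
  oracle.
- **Runge-Kutta oracle**: classic fixed-step RK4, step ≤ 0.01 year, used
  in tests only.  The non-differential and rate-ratio ODEs preserve
  [0, 1], so leaving it raises; the m₁/m ODE does not when the mortality
  inputs are mutually inconsistent — the packaged life-table rates,
  extrapolated beyond the observed 20–64 range, cross near age 72 and push
  the exact solution slightly above 1 past age ~80 — so that variant warns
  and continues.
- **Life tables**: 5-year survivor columns convert by
  `q₁ = 1 − (S_{k+1}/S_k)^{1/5}` at the group midpoint (the last group has
  no successor and is dropped); OLS of `log q₁` on age gives the Gompertz
  coefficients.  The fitted log-probability line is used directly as the
  log mortality rate — at working-age values of q the two agree to first
  order, and this convention reproduces the reference coefficients of the
  worked example exactly.
- **Rate-ratio curve**: `R(a) = max{exp(log r₀ − (a − a_ref)(log r₀ −
  log 2)/s), floor}` — log-linear decline from r₀ = 6.5 at age 20 reaching
  2 at age 70 (s = 50), floored at 1, matching the register-based excess
  mortality of diabetes.  The family cannot express a constant ratio of 1;
  code needing R ≡ 1 can pass any callable.

## Synthetic data and what the simulations show

`previnc.simulate` draws counts from the estimators' exact generative
model: scenario prevalence at the group midpoints, independent binomial
cells, seeded generator (replicate r uses seed + r, so runs are
sliceable).  Defaults mirror the worked examples: 5-year groups over
20–64, roughly 2 000 persons per group (the coal-miner table's scale);
recovery studies for the surface model use the diabetes table's own group
sizes (the 2009 column, reused for both simulated years) and its fitted
surface as truth.  Because the generator shares the estimators'
assumptions, passing recovery and coverage tests demonstrates internal
consistency — correct likelihood, optimizer and intervals — not robustness
to shared-cohort correlation between age groups, secular mortality trends,
remission, or misspecified mortality inputs, none of which are simulated.

Observed behaviour at these designs: Wald coverage for the incidence slope
is ~0.93–0.94 at coal-miner sample sizes (slightly below nominal, as
expected for a two-parameter Wald interval at moderate n), RMSE scales as
1/√n, and surface coefficients are recovered within 3 SE in ≈100% of
replicates at diabetes sample sizes.

## Design decisions and limitations

- The representative age of a group is its midpoint; prevalences are
  proportions internally, percent only at I/O boundaries; a stated
  prevalence column in an input file is always recomputed from c/n.
- Calendar time enters the surface centered at the reference year
  (t − 2009 ∈ {0, 1} for the diabetes data): the conventional starting
  values are only plausible on a centered scale, and the intercept then
  refers to the reference year.
- With a single year of data the surface drift β₁ is unidentified; the
  model requires a year column and leaves fixing β₁ to the caller.
- The differential-mortality estimate is conditional on the supplied m₁
  and m being error-free; propagating their sampling uncertainty (e.g. by
  influence functions) is out of scope, as are remission (non-chronic
  conditions), time-dependent incidence i(t, a), profile-likelihood
  intervals and Bayesian inference.
- Estimates at old ages lean on mortality rates extrapolated beyond the
  ages they were fitted on; the m₁/m model in particular can then imply
  prevalences above 1 (see the oracle note above), which should be read as
  a misspecification signal, not a numerical bug.
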