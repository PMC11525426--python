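# Methods

## The moment identities and what checking them establishes

For two hypotheses with marginal likelihoods p(E|H₁), p(E|H₂) over a common
sample space, the Bayes factor BF₁₂(E) = p(E|H₁)/p(E|H₂) satisfies

    E[BF_ft | H_t] = 1                          (Turing)
    E[BF₁₂^k | H₁] = E[BF₁₂^{k+1} | H₂],  k ≥ 0  (Good)

both by the same one-line telescoping argument: multiplying BF₁₂^k by the
true-hypothesis density and summing moves one power of the ratio across the
conditioning hypothesis.  The identities are *exact at every sample size*;
they fail only when some outcome has positive probability under one
hypothesis and zero under the other (a "universal generalization" such as
θ = 1).  The package treats that case as a first-class diagnostic:
`support_overlap_check` enumerates the offending outcomes,
`exact_bf_moment` warns when it skips them, and `run_full_check` refuses
the pair unless explicitly overridden.

A passing check is evidence that the *procedure* computing the Bayes factor
is consistent with the prior-predictive distribution it claims to
integrate over.  It is a necessary condition, not a proof: an error that
preserves the moments (e.g. a permutation of outcome probabilities) would
pass, and a check at one n says nothing about another n.

## Binomial models

Marginal likelihoods are closed-form: point hypotheses give the binomial
pmf (with the 0⁰ = 1 convention so θ ∈ {0, 1} is well defined), beta priors
give the beta-binomial, and truncated beta priors multiply in the ratio of
posterior-to-prior interval masses of the regularized incomplete beta.
Interval masses are differenced on whichever tail of the incomplete beta is
small (I_x(a,b) = 1 − I_{1−x}(b,a)); otherwise narrow intervals deep in a
tail lose all precision and the marginals stop summing to 1.

`exact_bf_moment` enumerates k = 0..n in log space (capped at n = 10,000 —
enumeration cost, not overflow, is the binding constraint).  It is the
oracle for every simulated moment: at m = 100,000 the simulation study's
batch estimates agree with enumeration within Monte-Carlo error, which is
the package checking itself by the very method it implements.

Truncated-beta sampling is inverse-CDF restricted to [lower, upper]:
uniform draws between the endpoint CDF values pushed through the beta
quantile function.  Exact, rejection-free, and vectorized.

## One-way ANOVA Bayes factor

Model under H₁: y = α1 + Xτ + ε with ε ~ N(0, σ²I), Jeffreys priors
p(α, σ²) ∝ 1/σ², effect prior τ ~ N(0, g σ² I), and a scaled inverse-χ²
hyperprior with 1 degree of freedom and scale r² on g (equivalently
g = r²/z² with z standard normal, making each contrast marginally
Cauchy(0, rσ)).  H₀ drops the effect term.  Named scales: medium r = 1/2,
ultrawide r = 1.

The design X maps the centered group-indicator matrix onto an orthonormal
sum-to-zero contrast basis of R^J.  Its columns are orthogonal to the
intercept; for balanced data XᵀX = n_g I.  This is deliberate: the g-scaled
prior then lives on *group-mean-scale* contrasts, the convention used by
the default one-way ANOVA Bayes factor in mainstream software, and the one
under which the reference results for this design (mean BF₀₁ ≈ 8.18 under
the null, second moment ≈ 8.15 under the alternative, misspecified mean
≈ 3.16) are reproduced.  An orthonormal-column design was considered and
rejected: it corresponds to a much tighter effect prior (the same g spread
over unit-norm columns) and yields a mean null-generated BF₀₁ of about
1.36 — a different test, not the reference one.

Integrating α, σ², τ analytically leaves

    BF₁₀(g) = det(I + g XᵀX)^(−1/2) · [ (yᵀCy − yᵀX(XᵀX + I/g)^{−1}Xᵀy) / yᵀCy ]^(−(N−1)/2),

a function of scale-free quadratic forms only, hence exactly invariant to
shifting or rescaling y (tested to 1e−10).  Internally the second factor is
evaluated as SSE + Σᵢ cᵢ² t/(λᵢ(λᵢ+t)) with t = 1/g, which is free of the
catastrophic cancellation the literal `SST − quad` form suffers when the
residual sum of squares is many orders below the total.

### Numerical integration over g

* `jzs_bf10` (single dataset): adaptive quadrature on u = log g, where the
  integrand is smooth and unimodal; the integrand is shifted by its maximum
  before exponentiation so arbitrarily extreme datasets stay in range.
  Relative tolerance 1e−8 enforced via the quadrature error estimate;
  non-convergence raises a failure (counted, never recoded, by the engine).
* `log_jzs_bf10_batch` (many datasets, shared layout): a fixed composite
  Gauss–Legendre grid on u ∈ (−40, 80), panels of width 1.5 with 8 nodes
  each.  The integrand's peak has O(1) width in u wherever the heavy-tailed
  hyperprior and the data place it, so a uniform panel width resolves every
  dataset; agreement with the adaptive path is pinned at 1e−7 absolute in
  log in the tests.  Everything stays in log space end to end: under the
  1-df hyperprior, prior-predictive effect draws routinely produce
  |log BF| in the hundreds or thousands, far outside float range.

Cross-checks (all in the test suite): a brute-force three-dimensional
numerical integration of both marginals over (α, τ, log σ²) on an N = 6 toy
reproduces the conditional Bayes factor to 1e−6 relative; Monte-Carlo
averaging of the conditional BF over g draws matches the quadrature within
sampling error on ten independent toys.

### Generators

`simulate_anova_h1` draws g = r²/z², then contrasts τ ~ N(0, g·σ²·I), then
balanced Gaussian noise; `simulate_anova_h0` sets τ = 0.  Noise and effects
use separate child streams of the seed, so the two generators coincide as
r_gen → 0 under the same seed.  Defaults are the reference design: J = 3
groups of 50, σ² = 0.5, r_gen = 1/2, intercept 0 (every computed quantity
is invariant to the intercept, so its value is immaterial).

The effect prior is scaled by σ² (`scale_effects_by_sigma2 = True`) so that
generation matches the analysis prior exactly — the condition under which
Turing's identity holds.  A literal "τ ~ N(0, g)" mode is retained for
sensitivity analysis; with σ² = 0.5 it is a *misspecified* generator and
the check correctly fails on it.

What the generator does not emulate: unbalanced designs (the BF accepts
them; the generator does not produce them), non-Gaussian noise,
heteroscedasticity across groups, and dependence between observations.  A
passing check on these synthetic conditions validates the *computation* of
the Bayes factor under its own model; it says nothing about model fit to
any real dataset.

## Check engine

`run_bf_batch` simulates m datasets under one hypothesis, scores each with
the pair's Bayes factor oriented toward a chosen hypothesis (reversing the
orientation inverts every value exactly), and applies an explicit policy to
undefined values.  Three replicate outcomes are distinguished:

* **value** — finite positive Bayes factor;
* **undefined** — a 1/0 Bayes factor (e.g. a saturated posterior quantity
  in a model-averaged procedure).  Default policy `recode_max_plus_one`
  replaces each with one plus the highest observed finite value; `drop`
  and `fail` are available since any recoding is a workaround;
* **failed** — numerical breakdown of the procedure.  Failed evaluations
  are excluded and counted, never recoded.

Verdicts: Turing's identity passes when |mean − 1| ≤ 3 mc_se, with mc_se
the sample-SD Monte-Carlo standard error; Good's identity compares adjacent
raw moments within 3 root-sum-square standard errors.  The 3-sigma
multiplier is configurable because no canonical tolerance exists for
"close to 1".  When the value skewness exceeds 10, a heavy-tail caution is
attached: the standard error estimate itself is then unstable and the
verdict should be read with care.  This matters in practice — generating
under a *point* hypothesis leaves rare outcomes carrying enormous Bayes
factors for the general model, and the running mean can sit far from 1 for
any practical m.  The engine therefore defaults to generating under the
general model, and the full workflow orients the checked Bayes factor in
favor of the specific one.

The universal-bound table reports, for each α, the empirical frequency of
BF_false ≥ 1/α against the bound α implied by Turing's identity plus
Markov's inequality; violations within binomial sampling fluctuation are
flagged, not raised.  The weight-of-evidence summary reports the mean and
SD of log BF (the additive, symmetric evidence scale) and the raw-value
skewness as a log-normality diagnostic.

## Problem sizes and reproducibility

The package's own study conditions are m = 100,000 replicates per binomial
condition (n = 10, 50, 100) and m = 20,000 per ANOVA condition — the
binomial size matches the reference study, the ANOVA size is a tenfold
scale-down that the vectorized batch evaluator completes in seconds while
leaving Monte-Carlo standard errors small relative to every tolerance
used.  All randomness flows from one master seed through
`SeedSequence`-derived child streams (one per batch, recorded in outputs),
so reports, CSVs and checksums regenerate bit-identically.

## Known limitations

* The enumeration oracle exists only for the binomial family; for the
  ANOVA model the oracles are numerical (brute-force integration,
  Monte-Carlo over g) rather than exact.
* Good's identity at high orders is dominated by tail replicates;
  moments above order 3 are supported but excluded from default reports
  because their Monte-Carlo error at feasible m makes verdicts
  uninformative.
* The theorem-verdict machinery assumes independent replicates; it is not
  designed for sequentially monitored or adaptively stopped simulations.
* Undefined-value recoding necessarily distorts moments when undefined
  values are frequent; the counts are always reported so the reader can
  judge.
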