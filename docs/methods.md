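# Methods

## Model

The trait model is an ordinary logistic regression of a binary outcome Y on
a SNP G and K non-genetic covariates E₁…E_K,

    logit P(Y=1 | x) = η = β₀ + β_G G + Σ_k β_{E,k} E_k,      x = (1, G, E…).

Genotypes follow Hardy–Weinberg equilibrium with minor-allele frequency
p ∈ (0, 0.5] and one of three effect codings: additive (values 0/1/2 with
probabilities (1−p)², 2p(1−p), p²), dominant (0/1, P(1) = 1−(1−p)²) or
recessive (0/1, P(1) = p²).

Each covariate depends on G through a second-stage regression

    g₂(E[E | G]) = γ₀ + γ_G G,

with g₂ = logit for binary E and identity for continuous E.  A continuous
E is conditionally Normal given G; the second-stage model only pins the
conditional mean, and normality is the assumption that makes both the
marginal-variance decomposition and the representative quantile
construction well defined.  Multiple covariates are **conditionally
independent given G**; correlated covariate structures are out of scope.

Users supply only interpretable quantities.  Intercepts and nuisance scales
are gleaned:

* γ₀ (binary E): root of Σ_g P(g)·expit(γ₀ + γ_G g) = exposure rate,
  solved by Brent's method on [−50, 50] with xtol 1e−12.  The map is
  strictly increasing in γ₀, so the bracket is safe; robustness was
  preferred over a closed-form special case.
* γ₀, σ_{E|G} (continuous E): γ₀ = μ_E − γ_G·E[G] and
  σ_{E|G}² = σ_E² − γ_G²·Var(G) when the marginal (μ_E, σ_E) is given;
  σ_E² ≤ γ_G²·Var(G) is rejected as infeasible.  Supplying both σ_E and
  σ_{E|G} is rejected as over-specified rather than silently resolved.
* β₀: root of E_{F_x}[expit(η)] = K (the disease prevalence), with the
  expectation exact over discrete covariates and 64-node Gauss–Hermite
  quadrature per continuous covariate.  Quadrature rather than Monte Carlo
  keeps the resolution deterministic; a 10⁶-draw Monte Carlo mean is used
  only as a test oracle.

## Study designs

Prospective designs use the population covariate law F_x directly.  A
retrospective case–control design with case fraction φ changes two things:

1. the covariate law becomes φ·P(x|Y=1) + (1−φ)·P(x|Y=0), with
   P(x|Y=1) ∝ expit(η)·P(x) — computed by exact cell reweighting for
   all-discrete designs and by rejection sampling from F_x otherwise
   (acceptance probability expit(η) or 1−expit(η); an efficiency below
   1e−4 aborts with a diagnostic);
2. the working intercept becomes β₀* = β₀ + log(φ/(1−φ)) − log(K/(1−K)),
   the intercept of the prospective logistic model fitted to case–control
   data (Prentice–Pyke).  β₀* enters the information weights; the slopes
   are unchanged.

Because the intercept of a case–control analysis is not identified by the
user's β₀, retrospective resolution always re-gleans β₀ from the
prevalence and ignores a user-supplied value; power is therefore exactly
invariant to it.  In prospective mode a supplied β₀ wins over gleaning.

## Power and sample size

With unit information I₁(β) = E_{F_x}[w(η)·x xᵀ], w = expit(η)(1−expit(η)),
the variance of the genotype estimate at sample size n is
V_{G,n} = [(n·I₁)⁻¹]_{G,G} and the two-sided Wald power is

    Φ(−z_{1−α/2} + β_G/√V_{G,n}) + Φ(−z_{1−α/2} − β_G/√V_{G,n}).

Column order is fixed to (1, G, E…) throughout, so the G entry is always
index 1.  V_{G,n} is obtained by solving the information against the G
basis vector rather than full inversion; condition numbers above 1e12
warn, singular matrices raise.  At β_G = 0 the formula returns α to
machine precision regardless of I₁.

**Semi-simulation (SS).**  I₁ is averaged over B i.i.d. draws from the
design-induced covariate law; B defaults to 10 000 (seed-to-seed SD of the
power < 0.01 there; B < 10 000 warns, B < 1000 is rejected).  Cost is
independent of the target n.  Within one n-grid or sample-size search a
single draw is reused: this trades a common Monte-Carlo offset for a
smooth, monotone power curve and a much faster search.  Sample size is
found from the one-term normal-approximation seed
n₀ = (z_{1−α/2}+z_{power})²·[I₁⁻¹]_{G,G}/β_G², then integer bisection on
the full two-term formula; the returned n* satisfies power(n*) ≥ target >
power(n*−1) exactly.

**Representative dataset (RD).**  A deterministic covariate table of size
n: every discrete cell (G × binary Es) receives the largest-remainder
(Hamilton) apportionment of n·P(cell) under the design law — the scheme
preserves Σ = n exactly; a positive-probability cell that rounds to zero
warns, since its stratum drops out of the information.  Within each
genotype stratum of size n_i a continuous covariate takes the quantile
scores γ₀ + γ_G g + σ_{E|G}·Φ⁻¹[(j−0.375)/(n_i+0.25)], j = 1…n_i.  With
two or more continuous covariates, later columns are permuted by a
fixed-seed permutation within the stratum, since pairing sorted quantile
sequences would fabricate rank correlation between conditionally
independent covariates.  Each row is expanded to outcomes 0 and 1 with
weights (1−expit(η), expit(η)); because the paired weights sum to one, the
weighted information at the true β is Σ_i w(η_i)·x_i x_iᵀ.  The weighted
MLE equals the true β at these weights (the weighted score vanishes
there), so the information is evaluated directly instead of running IRLS;
the equivalence is asserted in tests against a weighted GLM fit.  For
retrospective designs the cell law is the retrospective mixture and η uses
β₀*; with continuous covariates the genotype margin is tilted exactly (by
quadrature) while the within-stratum quantile values keep the population
conditional law — an approximation that is exact in the all-discrete case
and untested territory for retrospective-with-continuous designs, which no
built-in scenario exercises.  Sample-size inversion rebuilds the RD per
candidate n (doubling + bisection + a local sweep absorbing the O(1/n)
rounding jitter).

**Choosing between them.**  RD is deterministic but O(n); SS is O(B) and
noisy at the ~0.005 level.  For n beyond a few tens of thousands SS is the
practical choice, which is why it is the default method.

## The empirical oracle

`oracle` simulates complete studies: prospective — x ~ F_x, Y ~
Bernoulli(expit(η)); retrospective — exactly round(φn) cases from
P(x|Y=1) and the rest from P(x|Y=0).  Fits use hand-rolled Newton–Raphson
(gradient norm < 1e−8, ≤ 50 iterations, weights clipped at 1e−12);
separation or non-convergence flags the replicate, which is dropped and
counted (> 5% failures warns) — at the benchmark's n ≥ 600 and MAF 0.1
failures are essentially absent.  The Wald statistic β̂_G²/[I_X(β̂)⁻¹]_{G,G}
is referred to χ²₁.  One master `SeedSequence` spawns per-replicate
streams, so each replicate is independent of the replicate count.
`benchmark_table1` compares SS and RD power with the empirical power over
the default grid {600, 1000, 2000, 3000, 4000, 5000, 6000, 8000, 10000}
(the benchmark range 600–10 000 fixes only the endpoints; this 9-point grid
is the package's choice) and reports per-method average and maximum
absolute error.

## What the built-in scenarios do and do not show

The three scenarios (see `binpower.scenarios`) share MAF 0.1, dominant
coding and prevalence 0.2, and differ in covariate structure and design:
case–control without covariate (β_G = log 1.5), prospective with a binary
covariate (exposure 0.3, β_E = log 2.5, γ_G = log 0.2, β_G = log 1.5), and
prospective with a conditionally standard-normal covariate (γ_G = log 0.5,
β_E = log 2.5, β_G = log 1.3).  They emulate single-SNP planning with one
influential covariate under an idealized F_x: exact HWE, a correctly
specified second-stage model, conditional normality, no missingness,
no genotyping error, unrelated individuals.  Passing benchmarks therefore
show that the estimators recover the power of the *assumed* model, not
that the model describes any particular cohort.  Known residual effect:
with a strong continuous covariate the asymptotic power overshoots the
finite-sample empirical power by up to ~0.02–0.03 around mid-to-high
powers (n ≈ 6000–8000 in the third scenario); this is a property of the
Wald asymptotics, visible in the benchmark's maximum-AE column, and is
not removed by increasing B.

## Numerical choices and limitations

* Tolerances: root finders 1e−12 (xtol); IRLS gradient 1e−8; information
  condition-number warning at 1e12.
* Ties in largest-remainder apportionment break by cell order
  (deterministic).
* Degenerate inputs: MAF outside (0, 0.5], probabilities outside (0,1),
  b < 1000, replicates < 100, n below the parameter count and β_G = 0 in
  sample-size searches all raise named errors.
* The empirical rejection sampler is impractical for extreme prevalence
  (< ~1e−4) in retrospective continuous designs; exact enumeration covers
  the discrete case.
* Out of scope: G×E interaction power, probit link, correlated covariates
  given G, non-HWE genotype laws, related individuals, continuous traits.
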