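# Methods

## Model and design

The Weibull–Fréchet distribution WFr(a, b, α, β) arises by driving a
Weibull generator with a Fréchet baseline. Writing `x = (α/y)^β`,

    F(y) = 1 - exp{ -a [exp(x) - 1]^(-b) },   y > 0,

with shape parameters `a, b, β` and scale `α` (same units as time). Setting
individual parameters to 1 or 2 recovers several named sub-models (Weibull
inverse-exponential, exponential Fréchet, Weibull inverse-Rayleigh, …);
these are not wrapped separately — fix the parameters yourself.

Data arrive as a progressive type-II censored sample: `n` units on test,
`R_i` survivors withdrawn at the `i`-th failure, stopping at failure `m`
with `R_m` absorbing the remainder, so `m + Σ R_i = n`. The package
represents the removal plan (`ProgressiveScheme`) separately from the
observed failure times (`CensoredSample`) and validates both invariants
(removals accounting, strict ordering) at construction.

## Likelihood and maximum likelihood

The censored log-likelihood is `ℓ = Σ_k [log f(y_k) + R_k log r(y_k)]`, up
to an additive constant depending only on the scheme. The score equation in
`a` is linear and solves in closed form (`profile_a`), reducing the
optimisation to (b, α, β). The analytic score is derived directly from ℓ
and certified in the tests against central finite differences to 1e-6
relative at random parameter points; the observed information is computed
by central differences *of the analytic score* (step `1e-5·max(1, |θ|)`,
symmetrised), keeping one source of truth for derivatives.

### The boundary spike, and what "the MLE" means here

The four-parameter likelihood is unbounded: as α approaches the smallest
observation from below with β → ∞ (and a, b → 0 accordingly), ℓ → ∞ while
the implied law degenerates. With small m there may be *no* interior
stationary point at all — this is demonstrably the case for the packaged
15-point censored example, where multi-start root searches of the profiled
score and a dense grid scan all escape to the spike. The estimator
implemented is therefore the **local maximiser reached by ascent**, the
same convention used for Gaussian mixtures and three-parameter threshold
models:

* starts: a coarse grid over (b, α, β) scaled by the data median, refined
  by a short (150-iteration) Nelder-Mead run, or a user-supplied `init`
  (simulation studies start at the truth, the standard warm start for
  Newton-type estimators);
* ascent: damped Newton on log(b, α, β) with eigenvalue-shifted steps when
  the Hessian is not negative definite, line search requiring monotone
  likelihood (or gradient) improvement;
* termination: gradient sup-norm < 1e-8 (log scale) → `converged=True`;
  iterates leaving `|log θ| > 12`, or an unusable Hessian/gradient region,
  are classified as escapes and reported `converged=False` with the score
  norm and iteration count. Nothing is raised: downstream consumers decide.

Weak identifiability is the second structural fact: distinct parameter
4-tuples can produce nearly indistinguishable distributions, so raw
parameter estimates are unstable (and finitely biased) even when the fitted
*law* is accurate. Functionals such as r(t), h(t) and the CDF are the
well-determined quantities; tests assert recovery accordingly.

## Confidence intervals

Parameter intervals are `θ̂ ± z_{δ/2}·se` with standard errors from the
inverse observed information. Intervals for r(t) and h(t) use the delta
method with analytic gradients of both functionals. Bounds are **not**
truncated to the parameter space: in small samples the upper r(t) bound can
exceed 1 and lower bounds can be negative, which is reported as such (it
reproduces the published presentation and makes the quality of the normal
approximation visible). Default evaluation time `t = 0.5` (years, for the
packaged data).

## Parametric bootstrap

Both methods regenerate progressive samples from the fitted law under the
original removal scheme and refit each replicate (warm-started at the
original estimates). Boot-p takes nearest-rank percentiles
(`N·δ/2`, `N·(1-δ/2)`, clamped) of each quantity's replicate column; Boot-t
studentises each replicate with its own observed-information/delta standard
error and rescales by the original standard error. Replicates whose refit
fails (or, for Boot-t, yields non-positive variances) are dropped and
counted; above 20% drops the run aborts with an error rather than return an
interval from a biased subset. Default `N_boot = 1000`. Expect aborts on
small fragile datasets — with n ≈ 46 complete observations roughly a
quarter of resamples from the gastric fit have no interior MLE; that is a
property of the model, and the error message says so.

## Bayesian estimation

Priors are independent Gamma(shape, rate) on each parameter; defaults
`shape = rate = 1e-4`, proper but near-flat. The full conditional of `a`
is Gamma(m + c₁, k₁ + Σ (R_k+1)[exp((α/y_k)^β)-1]^(-b)) and is drawn
exactly; b, α, β are updated one at a time by random-walk
Metropolis–Hastings with normal proposals centred at the current value.
Proposal standard deviations default to the square roots of the MLE
asymptotic variances (`default_proposal_scales`), fixed across iterations;
negative proposals are rejected through the −∞ log-kernel contract
(equivalent to zero prior mass), not resampled. Each retained state is
mapped to r(t) and h(t), so posterior summaries of the lifetime
characteristics need no post-processing. Defaults `N = 11000` total with
`M = 1000` burn-in (10000 retained). Acceptance rates are reported;
rates below 1% trigger a warning. No further convergence diagnostics are
built in — dump the chains and inspect them for serious work.

Point estimation under balanced losses mixes the MLE ψ̂ (weight w) with the
posterior: BSEL gives `w·ψ̂ + (1-w)·E[ψ|data]`; BLINEX gives
`-(1/q)·log{w·e^(-qψ̂) + (1-w)·E[e^(-qψ)|data]}` with the exponential
moment computed by log-sum-exp so large |q·ψ| cannot overflow. `w = 1`
returns the MLE exactly; `q → 0` recovers BSEL. Credible intervals are the
`⌈N·δ/2⌉` and `⌈N·(1-δ/2)⌉` order statistics of the retained draws.
Posterior summaries use sample (n−1) variance, bias-corrected skewness, and
a Gaussian-KDE mode with Silverman bandwidth.

## Simulator

`generate_progressive_sample` uses the uniform-transformation algorithm:
independent uniforms `W_i` are powered by `1/(i + R_m + … + R_{m-i+1})` and
cumulated into the joint law of the progressively censored uniform order
statistics, then mapped through the WFr quantile. The direct physical
mechanism (`apply_progressive_censoring`: observe the minimum, withdraw
`R_i` survivors uniformly at random) is implemented independently and the
two are checked against each other in distribution — and against plain iid
sampling in the no-removal case — in the test suite. Random removal plans
use sequential conditional binomials with the last entry absorbing the
remainder. Ties in real data are broken by stable input order.

## Monte-Carlo study harness

`run_study` is a pure function of its configuration: a root generator
seeds one child stream per design and one per replicate, so results are
bit-reproducible and independent of evaluation order. Per replicate it
simulates a sample at the truth, fits by MLE (warm-started at truth) and
optionally runs the MCMC estimators, accumulating the mean squared error of
each estimator of (a, b, α, β, r(0.5), h(0.5)).

Two exclusion rules, both counted and reported: replicates whose fit does
not converge, and replicates converging to a *divergent* remote stationary
point — any parameter more than a fixed factor (default 20×) away from its
true value. The second rule exists because the weakly identified model
occasionally yields estimates like α̂ ≈ 300 at truth 2.0 whose squared
error would single-handedly dominate a 200-replicate mean; trimmed MSEs
over non-divergent replicates are the meaningful consistency measure.
Default 200 replicates per cell keeps a three-design MLE study under ten
seconds; pass `replicates=1000` for the full-scale version.

Problem sizes used by the default validation runs: coverage of the 95%
β-interval at (n, m) = (100, 75) over 500 replicates; the consistency trend
over designs (30,15) → (50,30) → (100,75) at 200 replicates.

## Goodness of fit

`ks_statistic` is the two-sided empirical-process sup-distance
`max_i max{i/n - F(y_(i)), F(y_(i)) - (i-1)/n}`; `ks_pvalue` uses the exact
finite-sample two-sided Kolmogorov distribution (`scipy.stats.kstwo`), not
the asymptotic series — at n = 46 the two differ in the second decimal, and
the exact value is what standard software (and the published analysis of
the gastric data) reports.

## What the synthetic data do and do not show

The simulator emulates exactly the stochastic mechanism assumed by the
model: WFr lifetimes, faithful progressive withdrawal, no ties, no
covariates, no model misspecification. Passing tests therefore certify the
*internal* consistency of estimator and generator; they say nothing about
WFr adequacy for a given real dataset (that is what the KS machinery is
for), nor about robustness to misspecified censoring.

## Known limitations

* No MLE may exist for small censored samples (see the spike discussion);
  the package reports this honestly, and everything downstream of a
  converged fit (intervals, bootstrap, proposal scales) refuses to run on a
  non-converged one.
* Raw parameters are weakly identified; prefer functionals for scientific
  conclusions.
* Exact ties in observed times are rejected rather than jittered.
* The expected (rather than observed) Fisher information, profile-likelihood
  intervals, BCa bootstrap and MCMC convergence diagnostics beyond
  acceptance rates are out of scope.
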