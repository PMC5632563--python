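# Methods

## Design problem

A balanced complete-block stepped-wedge cluster randomised trial observes
`C` clusters over `T` periods with `m` measurements per cluster-period
(cross-sectional sampling: new individuals each period).  Every cluster
starts on control, finishes on intervention, and an equal-as-possible number
of clusters switches at each of periods `2..T`; when `C` does not divide
evenly over the `T - 1` steps, the remainder is assigned to the earliest
steps (this matches the only explicitly scheduled worked scenario, the 20
clusters over 8 steps stepping 3,3,3,3,2,2,2,2), and an explicit schedule
argument overrides the default.  Rows of the treatment-indicator matrix are
ordered earliest-switcher first; all computed quantities are invariant to row
permutations.

Analysis uses the standard cross-sectional linear mixed model with a fixed
period effect (`pi_1 = 0` for identifiability), a fixed treatment effect
`tau`, a random cluster intercept with variance `sigma_c2` and residual
variance `sigma_e2`.  The per-cluster covariance blocks are
`sigma_e2 * I + sigma_c2 * J`; the general model path (`build_hh_model` /
`information_general`) accepts arbitrary `D, Z, G, R`, so users with cohort
sampling or cluster-by-period random effects can supply their own covariance
structure, but no closed-form information is provided for those cases.

## Information and the canonical joint law

The sequential Wald statistics `Z_t = tau_hat_t sqrt(I_t)` are monitored at
the scheduled analyses.  `I_t` comes from the closed form in the treated-cell
summaries `U, V, W`; a generic GLS route computes the same quantity as the
reciprocal `(tau, tau)` entry of a generalised inverse of `D' Sigma^-1 D`
and is tested to agree to 1e-8 relative error on randomised layouts.  The
Moore–Penrose pseudo-inverse is used for rank-deficient nuisance blocks: it
is unique and symmetric, and only the `tau` entry needs to be well defined.
`Sigma` is inverted block-by-cluster (exact, not an approximation).  A design
is rejected as inestimable when no cluster is treated by the first analysis,
or — equivalently between both routes — when the treatment indicator is
confounded with the period effects (every cluster sharing one switch time).

Estimability granted, `E(Z_t) = tau sqrt(I_t)` and
`cov(Z_ti, Z_tj) = sqrt(I_ti / I_tj)`, so the score process
`S_t = Z_t sqrt(I_t)` has independent Gaussian increments.  All
boundary-crossing probabilities are computed by the classical recursion on
this score scale: the continuation sub-density is propagated analysis by
analysis with Gauss–Legendre quadrature (192 nodes per stage by default;
results are identical to 1e-10 from 128 through 768 nodes), grids truncated
at ±8 marginal standard deviations, and crossing probabilities evaluated with
exact normal tail functions so infinite or far-out boundaries remain exact.

## Error-spending boundaries

Type-I and type-II error are allocated by `e(z) = alpha z^gamma_e` and
`f(z) = beta z^gamma_f` in the information fraction `z = I_t / I_T`.  At each
interim analysis the efficacy boundary is the root (bracketed in [-15, 15]
on the Z scale, absolute tolerance 1e-10) equating the first-upper-crossing
probability under `tau = 0` to the incremental type-I spend, and the futility
boundary equates the first-lower-crossing probability under `tau = delta` to
the incremental type-II spend; both roots depend only on the previous
continuation state, so their order within an analysis is immaterial.  The
final efficacy boundary spends the entire remaining `alpha` (prioritising the
type-I error), and the final futility boundary is set equal to it so a
decision is forced.  One-direction designs hold the other boundary at ±inf
at every interim and spend the corresponding error wholly at the final
analysis.  An incremental spend that is numerically non-positive yields an
infinite boundary (no stopping at that analysis).  If a futility boundary
exceeds the efficacy boundary at an interim — which happens when `m` is far
above the power requirement, so the type-II budget is exhausted too easily —
the solver raises an infeasibility error rather than clamping; the
sample-size search interprets that condition as "power target exceeded" while
bracketing.

Futility boundaries are binding: crossing one mandates acceptance.
Non-binding futility, other spending families, and two-sided hypotheses are
out of scope.

## Operating characteristics and sample-size search

The stopping-time/decision distribution `P(omega_R, psi_R | tau)` at any true
effect reuses the same recursion (boundaries and operating characteristics
are therefore mutually consistent by construction), with the conventions
stop-accept iff `Z <= f`, stop-reject iff `Z > e`.  From it follow the
rejection probability, the probability mass function of the total number of
measurements `M = m C omega_R`, its expectation and tail probabilities.

The minimal `m` with `P(reject | delta) >= 1 - beta` is found on a
continuous scale — the closed form accepts non-integer `m` — by bracketed
root finding (power is increasing in `m`), with the boundaries re-solved at
every candidate because the information fractions depend on `m` through
`sigma_e2 / m`; the root is then rounded up and re-verified at the integer.
This is the stated minimal-power rule for every stopping mode.  One published
worked-example table row pair (the efficacy-only designs on the {3,4,5}
schedule) reports larger `m` values than this rule produces; at those
published `m` our operating characteristics match the published expectations
to the cent, so the discrepancy concerns only the sizing rule for those rows,
and the package keeps the single documented rule uniformly (the same source's
efficacy-only design on {2,3,4,5} does follow it).  Exhaustive integer scans
over `C` or `T` are left to the user; the search here fixes the layout.

## Unknown variance: observed information, quantile substitution, simulation

In practice the variance components are estimated at each analysis and
`Z_t = tau_hat_t sqrt(I_hat_t)` uses the observed information — the closed
form evaluated at the fitted variances, identical to the reciprocal GLS
sampling variance of `tau_hat` (tested).  Fitting is exact ML or REML of the
individual-level model, computed on the sufficient statistics: cluster-period
means (residual variance `sigma_e2 / m`) plus the pooled within-cell sum of
squares.  The (restricted) likelihood is profiled to a bounded scalar
minimisation over the cell-level variance ratio `lambda = m sigma_c2 /
sigma_e2` (closed-form GLS for the fixed effects and the scale at each
`lambda`; `sigma_c2` truncated at zero when the optimum is on the boundary;
successively widened brackets up to 1e8 before a replicate is flagged
non-convergent, with flagged replicates excluded only while they remain at or
below 0.1% of the total, and an error otherwise).  Equivalence with a dense
individual-level likelihood optimisation and with statsmodels' MixedLM is
part of the test suite.

Quantile substitution maps each finite boundary `b` to `b*` preserving the
upper-tail probability between the standard normal and the Student t scaled
to unit variance (`sqrt((nu-2)/nu)` scaling, hence `nu > 2` required) with
the balanced-ANOVA degrees of freedom `nu_t = m C t - C - t`.  Note the
correction need not enlarge a boundary: at moderate `nu` the variance-1 t has
more central mass as well as heavier tails, and its 95% quantile lies
slightly *below* the normal's; at the `nu ~ 10^3` typical here the adjustment
is a fraction of a percent either way.

The Monte-Carlo engine generates trials under `mu = pi_j = 0` directly at the
sufficient-statistic level — cell means `tau X_ij + c_i + Normal(0,
sigma_e2/m)` and within-cell sums of squares `sigma_e2 * chi2_{m-1}` — which
is the exact joint law of the statistics the fit consumes, at roughly
`m`-fold lower cost than individual-level simulation.  Replicates run on
independent spawned substreams of a single base seed, so results are
reproducible and embarrassingly parallel.  The default study size is 10,000
replicates, the package's standard reporting scale for empirical rates (the
binomial standard error at rates near 0.05–0.09 is then about 0.003);
`n_reps` restores any other scale.

## What the generator emulates, and what it does not

The simulation engine reproduces exactly the model under which the designs
are derived: Gaussian responses, a single random cluster intercept constant
over time, equal cell sizes, no period-by-treatment interaction, zero period
effects (the analysis is invariant under additive period shifts, so this is a
convenience, not a restriction).  Real SW-CRT data can violate all of these —
decaying within-cluster correlation, unequal cluster sizes, secular trends
interacting with treatment, non-normal outcomes.  Passing tests therefore
certify the sequential machinery (boundaries, error rates, sample sizes)
under the working model, not robustness to model misspecification: a design
whose operating characteristics are exact here can still miss its nominal
error rates in the field if the working model is wrong.

Known-variance monitoring of simulated canonical Z paths reproduces the
designed `alpha` and power within Monte-Carlo error (the suite checks 10^5
paths; the quadrature is also validated against 10^6-path simulation
cell-by-cell).  With *estimated* variances and only four clusters, the
empirical type-I error exceeds its nominal level; REML estimation removes
more of that inflation than quantile substitution does, inflation shrinks as
the interim analyses move later, and the simulation study in the test suite
reproduces the published empirical rates of the motivating study within three
binomial standard errors at 10,000 replicates, plus those orderings.

## Numerical conventions

- Boundary roots: Brent's method, bracket [-15, 15] on the Z scale,
  xtol 1e-10; spend increments below 1e-12 give infinite boundaries.
- Quadrature: 192 Gauss–Legendre nodes per stage, ±8 SD truncation.
- Sample-size search: continuous root to 1e-4 in `m`, then ceiling and
  integer re-verification; default cap `m <= 10^6`.
- Variance-ratio optimisation: bounded Brent on `lambda in [0, 1e2..1e8]`,
  xatol 1e-8; boundary solution `lambda = 0` checked explicitly.
- Ties at boundaries follow the stopping rules verbatim: accept iff
  `Z <= f_t`, reject iff `Z > e_t` (measure-zero distinction, but the
  simulation engine uses the same convention as the integrals).
- Expected sample sizes are reported rounded to two decimals in table
  outputs; full precision is kept internally.
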