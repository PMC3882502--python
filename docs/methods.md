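# Methods

## Probability model

Responses are normal with unit variance; all effects are standardized
(σ = 1 throughout — design tables for other σ follow by rescaling δ, m0
and v0).  The control effect is fixed at 0.  A screening trial allocates
n1 patients to each of K experimental arms and a shared control;
z-statistics are Z_i = (X̄_i − X̄_0) / √(2/n1).  Treatment effects are
exchangeable N(m0, v0²) draws, independent across treatments and across
screening cycles (an inexhaustible pipeline).  All program-level
quantities are prior-predictive: sampling distributions averaged over the
prior.

Parameters and defaults (the reference scenario used in the examples and
tests): m0 = 0, v0 = 0.1 (effect-size units), δ = 0.25 (standardized
clinically relevant difference), one-sided α = 0.025, power 1−β = 0.9.
The case-study scenario uses m0 = −0.067, v0 = 0.165 as given inputs.

## Top-treatment designs (single-stage confirmation)

The probability that a given treatment is selected conditions on its
screening sample mean x, marginally N(m0, v0² + 1/n1): the K−1
exchangeable competitors are independently beaten with probability
Φ_m(x) (the CDF of that same marginal), and integrating the control mean
N(0, 1/n1) analytically turns the threshold event Z_i > c1 into
Φ(√n1 (x − c1√(2/n1))).  One adaptive quadrature (domain ±8 marginal SD,
absolute tolerance 1e−10) gives the selection probability.

The joint selection-and-success probability weights the same kernel by
the confirmatory power R(μ) = Φ(μ√(n2/2) − z_{1−α}) with
n2 = 2(z_{1−α} + z_{1−β})²/δ².  The inner expectation of R over
μ | x (normal posterior) is itself a normal CDF, so the nominally
two-dimensional integral collapses to one dimension — a large speed win
during optimization with no accuracy cost.

ESS uses the renewal identity
ESS = [(K+1)n1 + 2 n2 E(P1)] / E(P2), valid because cycles are i.i.d.
n2 is continuous by default (`integer=True`/`--integer-n2`-style flags
round up; the difference is below 0.3% of ESS).

Screening operating characteristics: the family-wise error rate
P(max Z > c1 | all μ = 0) integrates out the shared control mean
(equicorrelated ρ = 1/2 normals); power at (δ, 0, …, 0) conditions on the
effective arm's sample mean.

## All-interesting designs (single-stage multi-arm confirmation)

Given the screening control mean u, treatments pass independently with a
common probability, so the number of passers is Binomial(K, q(u)) and the
2^K subsets collapse to K+1 counts.  A confirmatory trial with i arms
uses the Dunnett critical value c2(i) (root of the equicorrelated-normal
FWER equation, solved to 1e−10 after conditioning on the shared control)
and per-arm size n2(i) = 2(c2(i) + z_{1−β})²/δ², the closed form of the
*marginal* power requirement for a prespecified arm — not disjunctive
power, and not "selected as best".

A cycle confirms nothing when no arm passes or all passers miss c2(i).
Conditioning on both control means (screening u, confirmatory w) makes
treatments independent; each contributes a bivariate-normal rectangle in
its (screening mean, confirmatory mean) pair, which share the treatment's
true effect and hence covariance v0² (verified against brute-force
simulation).  The two outer integrals use 96-point Gauss–Hermite rules;
the bivariate CDF is a vectorized Owen's-T closed form.

ESS = Σ_i P(|I|=i) [(K+1)n1 + (i+1)n2(i)] / P(cycle success).  At K = 1
the rule coincides with top-treatment (checked to 1e−6 relative).

## Group-sequential confirmatory trials

Stage statistics at equal information increments have corr(Z_j, Z_k) =
√(j/k).  The triangular family on the z scale is u_j = C(1+t_j)/√t_j,
l_j = −C(1−3t_j)/√t_j with t_j = j/J; the final bounds coincide.

**Calibration convention.**  The shape constant C is chosen so that the
probability of *ever crossing the efficacy boundary* under μ = 0 equals
α, and the per-stage size g so the same crossing probability at δ equals
1−β — in both cases treating the futility boundary as non-binding
(ignored), the common regulatory stance that type-I error must hold even
if a sponsor ignores a futility stop.  Futility stops *are* applied when
computing expected sample sizes and program probabilities, so attained
error rates in conduct are slightly conservative; they are reported in
`GSBoundaries.attained`.  A `binding=True` flag calibrates both rates
with the futility boundary honoured instead.  The non-binding convention
reproduces the published two-stage design table within 0.6%, the binding
one within 1.7%; we default to the former.  No discrete-monitoring
("Christmas-tree") overshoot correction is applied — the discrete
boundary is calibrated exactly by numerical integration.

Stopping probabilities are multivariate-normal rectangle probabilities
(bivariate closed form for J = 2; scipy's MVN integration above that).
For the program ESS, conditioning on the selected treatment's screening
mean x keeps the confirmatory stage statistics jointly normal after
mixing over μ | x — the covariance is inflated by the posterior variance
— so the decomposition

ESS = [(K+1)n1 + E(N; ψ≠0, χ=0) + E(N; ψ≠0, χ=1)] / P(ψ≠0, χ=1)

needs only a one-dimensional outer integral (128-point Gauss–Hermite).
N*(j) counts both arms: 2 j g.  With J = 1 the whole construction
degenerates to the single-stage formulas (checked to 1e−8 relative).

MAMS generalisation: with i arms sharing one control, C is calibrated so
the family-wise efficacy-crossing probability under the global null is α
(two-dimensional Gauss–Hermite over the control's stage increments; arms
conditionally independent), and g from the marginal one-arm crossing
probability at δ.  At J = 1 this reduces exactly to (c2(i), n2(i)).
Implemented for J ≤ 2; more interim analyses would need the same
conditional-independence integral in higher dimension.

## Simulation engine

The dataset bank stores prior effect draws and design-independent
standard-normal increments (one per screening arm; one per confirmatory
arm and stage).  Sample means for any candidate (n1, c1) are formed by
exact rescaling, so all candidate designs in an optimization share common
random numbers and the simulated ESS surface is smooth enough for
Nelder–Mead.  Confirmatory conduct: arms are dropped at futility, the
trial stops at the first analysis with an efficacy crossing (if several
arms cross, the one with the larger final statistic is the confirmed
treatment), and the control accrues with the surviving arms.  The four
plug-in estimates (P(conduct), P(success | conduct), E[N | fail],
E[N | success]) enter the same renewal identity; Monte-Carlo standard
errors use the delta method on the ratio of means.

Program-level quantiles (e.g. the 95% quantile of total patients until
success) are simulated directly: independent cycles until first success,
vectorized across programs, with a bootstrap SE on the empirical
quantile.  Defaults: 100 000 bank replicates during optimization,
200 000 programs for quantile reporting — enough to put Monte-Carlo error
well inside the 3-4 significant figures quoted, while keeping a full
table reproduction on one CPU in minutes.

## Optimization protocol

Per K: Nelder–Mead on (log(n1−1), c1) — the transform enforces n1 ≥ 1
smoothly — from start (20, 0.5) with two deterministically perturbed
restarts; convergence at simplex tolerance 1e−4 / objective 1e−3
patients.  Then c1 is re-optimized one-dimensionally at the floor and
ceiling integers of n1 and the better integer design returned.  The scan
over K marks the argmin.  The surface is flat near the optimum (pinning
c1 = 0 at the reference optimum costs ≈ 0.2% ESS), so reported c1 values
are meaningful only to ~1e−2.

## What the generator emulates — and what it does not

The synthetic model is exactly the design-stage model: normal responses,
known unit variance, exchangeable normal effects, instantaneous outcome
observation, no dropout, no correlation between candidate treatments
(e.g. doses of one compound would violate this), and the same endpoint in
screening and confirmation.  Passing tests therefore validate the
computations under the planning model, not robustness of the planned
designs to variance misspecification, prior misspecification, delayed
outcomes or endpoint switching.

## Known limitations

* Binary / time-to-event endpoints only via normal approximation of the
  z-statistics; not implemented natively.
* Equal allocation (1:1 per arm, both phases) only.
* MAMS boundary calibration restricted to at most one interim analysis.
* The optimizer is local (restarted Nelder–Mead); published-table optima
  are reproduced, but global optimality is not guaranteed for unusual
  scenarios.
* Degenerate priors (v0 = 0) are supported in the analytic paths for
  checking; the optimizer assumes v0 > 0.
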