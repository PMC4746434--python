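# Methods

## Model

Likert-type instruments score a respondent on several correlated scales at
once. The package models such data with the multidimensional graded
response model (MGRM). Respondent *i* carries a latent trait vector
θ ∈ ℝ^H, distributed MVN(0, Σ) with unit variances and correlation matrix
Σ. Item *j* has discriminations a_j = (a_j1, …, a_jH) and strictly
increasing boundary parameters b_j1 < … < b_jK (K+1 ordered response
categories). The boundary (cumulative) probability of answering in
category k or above is the multivariate two-parameter logistic

    P*_jk(θ) = 1 / (1 + exp(−D Σ_h a_jh (θ_h − b_jk))),

with P*_j0 ≡ 1 and P*_j(K+1) ≡ 0, and category probabilities
P_jk = P*_jk − P*_j(k+1). D defaults to 1 (logistic metric); 1.7
approximates the normal ogive. Only *simple structure* is supported: each
item loads exactly one dimension, so each item is a unidimensional graded
item in its loading trait and the boundary parameters are scale-located as
usual. The printed form of the multivariate logistic shares one b_jk
across dimensions; under simple structure this is equivalent to the
unidimensional model per item, and the generator never produces anything
else (within-item multidimensionality is out of scope).

## Synthetic data generator

The generator emulates the study conditions of a three-scale Likert
instrument measured on four response categories:

* **Items.** L items in contiguous blocks of L/H per dimension (the
  assignment order is arbitrary for every statistic computed here; blocks
  are deterministic and independent of the random stream). Nonzero
  discriminations ~ U[1.1, 2.8]. Boundaries drawn from the three
  contiguous thirds of [−2, 2] — U[−2, −0.67], U[−0.67, 0.67],
  U[0.67, 2] — and the whole triple is redrawn until every adjacent gap is
  ≥ 0.5 (full-triple rejection keeps the within-interval marginals uniform
  conditional on acceptance; the acceptance probability is ≈ 0.86, and a
  10^5-redraw cap guards impossible configurations).
* **Simulees.** θ ~ MVN(0, Σ) with unit variances and a common
  off-diagonal correlation r ∈ {0.2, 0.5, 0.7} in the study design.
* **Responses.** One categorical draw per person-item pair from the
  model's category probabilities (a single multinomial trial).

Per-replication random streams are spawned from
`SeedSequence(master_seed, spawn_key=(L, N, round(1000 r), rep))`, so any
cell/replication is reproducible bit-exactly regardless of execution order
or parallelism.

The generator does **not** emulate: missing responses, guessing/slipping,
differential item functioning, testlet dependence, non-normal or skewed
trait distributions, or cross-loading items. Passing tests therefore speak
to estimator behaviour under a correctly specified, complete-data,
simple-structure model — not to robustness against any of the above.

## Calibration (MML-EM)

Item parameters and the latent correlation matrix are estimated by
marginal maximum likelihood with an EM algorithm; latent traits are
integrated over a fixed grid.

* **Quadrature.** Equally spaced univariate nodes on a bounded range
  (default 21 points on [−3.5, 3.5]; the desk-scale runs in this
  repository use 15, which reproduces the 21-point aggregates to well
  within replication noise), tensored over dimensions, with node mass
  proportional to the MVN(0, Σ) density, renormalized. A bounded
  rectangular rule is used rather than Gauss–Hermite nodes because a hard
  range restriction is incompatible with unbounded GH abscissae; the rule
  is low-order, so the marginal log likelihood shifts by ~1e−5 (relative)
  when the grid is doubled — immaterial next to sampling error at these
  sample sizes. A guard rejects grids beyond 10^7 nodes.
* **E-step.** Under simple structure the respondent likelihood factorizes
  across dimensions; per-dimension likelihood tables (computed in log
  space with per-respondent max shifts, categories floored at 1e−10) are
  combined on the tensor grid with the prior weights. This keeps the cost
  at O(N·L·m + N·m^H) per cycle and is underflow-safe at L = 240.
* **M-step, items.** Each item maximizes its expected complete-data log
  likelihood over (a, b_1, log-gaps): the log-gap reparameterization keeps
  the boundary ordering built-in and the objective smooth. Newton
  iterations (cap 20) with step halving; the Hessian comes from central
  finite differences of the analytic gradient; a bounded Powell search is
  the fallback for non-finite steps, and an item whose inner loop fails
  retains its previous values for that cycle (flagged in the notes).
* **M-step, correlations.** The latent correlation update maximizes the
  expected complete-data log prior Σ_q n̄_q log w_q(Σ) over unit-diagonal
  matrices (off-diagonals on a tanh scale, quasi-Newton, warm-started at
  the rescaled posterior second-moment matrix). The rescaled moment matrix
  itself is the exact update only for an *untruncated continuous* normal
  prior; on the bounded discretized grid its fixed point underestimates
  the correlations slightly, which is why it serves as a warm start rather
  than the update. With the exact step the procedure is a true EM: the
  marginal log likelihood is non-decreasing every cycle, and the EM fixed
  point coincides with a direct numerical maximization of the marginal
  likelihood (verified in the tests to 1e−3 in log-likelihood). Unit
  variances and zero means are fixed for identification; a configuration
  option fixes Σ at a supplied matrix instead.
* **Start values.** a = 1.5 on the loading dimension; b_k at the logit of
  the observed proportion below category k, clipped to [−3, 3] and nudged
  to keep gaps ≥ 0.05; Σ = I. Deterministic and scale-consistent.
* **Convergence.** Maximum absolute parameter change (items and
  correlations) < 1e−4, or 500 cycles; both configurable. `max_cycles=0`
  returns the start values with `converged=False`.
* **Standard errors.** Cross-product (outer product of gradients)
  approximation to the information of the marginal likelihood. By
  Fisher's identity the respondent score for an item is the posterior
  expectation of the complete-data score, which under simple structure
  needs only the posterior over the item's loading dimension. A singular
  information matrix yields +∞ standard errors and a failed fit.
* **Failure flag.** A fit is failed when EM did not converge, the
  information matrix is singular, or any item-parameter SE exceeds a
  threshold (default 1.0 — an operationalization of "unusually large"
  standard errors on the logit scale, where well-estimated items at these
  sample sizes show SEs an order of magnitude smaller; configurable).
  Failed replications stay in the output tables flagged `failed=True` and
  are excluded from every aggregate.

Degenerate inputs: out-of-range categories are an input error; an item
with an empty observed category proceeds under the probability floor and
is noted in the result; an item with a single observed category likewise
(its boundaries are then essentially unidentified and its SEs large).

## Recovery indices

Per replication and parameter class: bias = mean(est − true),
RMSE = √mean((est − true)²), and the Pearson correlation of true and
estimated values. Classes are a_1…a_H — the nonzero discriminations of
the L/H items loading each dimension — and b_1…b_K over all L items.
Structural zeros are excluded: they are fixed by the confirmatory
structure, and counting them would mechanically shrink bias/RMSE and
inflate correlations. (The alternative reading — dividing by the total
test length even for per-dimension discrimination classes — would shrink
every discrimination index by a factor of H; the per-dimension denominator
is the one consistent with indices reported "per dimension".) A
zero-variance vector makes the correlation undefined; it is reported as
missing.

## Study orchestration and ANOVA

The full design crosses L ∈ {30, 90, 240} × N ∈ {500, 1000, 1500, 2000} ×
r ∈ {0.2, 0.5, 0.7}, 30 replications per cell, new bank and simulees per
replication. Calibration exceptions inside a condition are captured as
failed rows, never aborting the run. The (L=240, N=500) cells are marked
excluded by explicit configuration (those calibrations produce unusually
large standard errors); an optional auto-exclusion flags any cell whose
failure rate exceeds a threshold.

Effect sizes come from a per-class, per-index three-way fixed-effects
ANOVA on replication-level values: sum-to-zero (effects) coding, Type-II
sums of squares (no a-priori factor ordering; the design after exclusions
is unbalanced), and

    η²_effect = SS_effect / SS_total,

where SS_total is the sum of all model sums of squares including the
residual — so all η² values, residual included, sum to exactly 1 on
balanced and unbalanced designs alike. A factor left with a single level
is dropped with a warning. Running means (cumulative means of each index
by replication count) reproduce the pilot diagnostic used to fix the
number of replications; marginal summaries first average within design
cells, then report mean and SD across cell means.

## Desk-scale problem sizes

The repository's own runs (tests, `scripts/acceptance.py`, `analysis/`)
use reduced scale chosen once: 15 quadrature points per dimension,
L ∈ {30, 90}, N ≤ 1500, and 3–15 replications per cell. Replications are
allocated by how noisy the aggregate is: 15 for the sample-size deltas
(differences of means), 10 for point aggregates and for the
minimum-over-cells correlation summary (a minimum over noisy cell means
is biased downward and stabilizes with replications), 3–8 in the test
fixture. Aggregates at this scale match the
21-point, 30-replication behaviour to within replication noise. The
L = 240 conditions (bias signature at N = 1000, failure at N = 500) take
hours per replication and live in `analysis/05_long_bias_L240.py`.

## Known limitations

* Only simple structure; no within-item multidimensionality, and the
  shared-boundary form of the multivariate logistic is never exercised
  beyond it.
* No person scoring (EAP/MAP), no item-fit statistics, no
  Metropolis–Hastings Robbins–Monro or adaptive quadrature.
* The rectangular quadrature is low-order; with very diffuse or very
  peaked posteriors (extreme discriminations, tiny samples) a denser grid
  or wider range may be needed.
* OPG standard errors are first-order asymptotic; they are accurate near
  the optimum at moderate N but are not a substitute for profile or
  sandwich intervals under misspecification.
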