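# Methods

## The question

Network meta-analysis (mixed treatment comparisons, MTC) estimates all
k(k−1)/2 pairwise relative effects of k treatments from a connected network
of randomized trials, combining direct and indirect evidence.  When every
pairwise contrast is screened for significance at a conventional
per-comparison level, the family-wise error rate — the probability that at
least one contrast is spuriously declared significant when no true
differences exist — can be far above the nominal level.  `mtcsim` measures
this by Monte Carlo: it builds null-hypothesis trial networks whose design
matches a published 12-treatment antidepressant evidence base (117 trials,
236 arms, 25,928 participants, overall response rate 0.57), network
meta-analyzes each replication, and tallies the number X of significant
contrasts per replication.

## Synthetic network generator (`mtcsim.synthetic`)

The trial-level table behind the published summary counts was never
deposited, so the generator emulates the design from its summary structure.
It conserves the totals exactly for every seed:

- 117 trials and 236 arms.  The 2 surplus arms beyond two-per-trial are
  realized as two three-arm trials (three-arm designs are the common
  multi-arm case in antidepressant trials; a four-arm trial would be the
  alternative reading and can be emulated via the config).
- 25,928 participants.  Arm sizes are apportioned by a symmetric gamma
  weight vector with coefficient of variation `dispersion` (default 0.25,
  so sizes vary realistically around the mean 25,928/236 ≈ 109.9), with a
  largest-remainder repair so the total is exact and every arm has at
  least one participant.  `dispersion = 0` gives a maximally even split.
- Connectivity.  The first k−1 = 11 comparisons realize a random spanning
  tree over the treatments; the remaining 106 trials draw treatment pairs
  uniformly at random.  A preferential-attachment exponent
  (`attachment_exponent`) is available for denser hub topologies but the
  documented default is uniform: no topology data were published, so the
  choice is explicit and overridable rather than a guess at the original
  adjacency.

What the generator does *not* emulate: the true comparison multiplicities
of the original network (some drug pairs had many head-to-head trials,
others none), per-trial randomization ratios other than those implied by
the size apportionment, and any correlation between trial size and
comparison.  Passing results therefore characterize networks *like* the
published one in size and connectivity, not its exact adjacency; headline
statistics are expected to be close, not identical.

## Null response model (`mtcsim.simulate`)

Under the null every participant responds with probability 0.57 regardless
of arm.  Responses are drawn as one Binomial(n, p) count per arm —
distributionally identical to per-participant Bernoulli draws and much
cheaper.  Alternatives for testing are log-odds shifts per treatment:
p(arm) = expit(logit(0.57) + effect).  Replication i of a run with master
seed s uses the dedicated PCG64 substream seeded (s, i), so any replication
can be regenerated in isolation and results are independent of evaluation
order and worker count.

## Bayesian MTC engine (`mtcsim.engine`)

The standard arm-based random-effects consistency model for binary data:

    r_ik ~ Binomial(n_ik, p_ik)
    logit(p_ik) = mu_i + delta_ik,   delta = 0 for the baseline arm
    delta_i ~ Normal(d_t − d_b, sigma²),  multi-arm covariance sigma²/2

with basic parameters d (log odds ratios versus the first treatment;
d_ref ≡ 0) and every other contrast derived by consistency,
d_st = d_1t − d_1s.  Priors are vague on the log-odds scale —
mu_i ~ N(0, 15²), d ~ N(0, 15²), sigma ~ Uniform(0, 5) — chosen to be flat
relative to any achievable log odds ratio, mirroring common MTC defaults.
The baseline arm is the first-listed arm of each trial; the global
reference is the first treatment in the network's list.  Zero cells need
no continuity correction: the binomial likelihood handles them natively.

### Sampler

Metropolis-within-Gibbs with four move types per sweep:

1. Trial baselines mu_i: independent adaptive random-walk steps, vectorized
   across trials (they are conditionally independent).
2. Random effects delta: adaptive random-walk steps against the binomial
   likelihood and the conditional normal prior given the trial's sibling
   effects, evaluated in within-trial position passes so all updated
   components are conditionally independent.
3. Basic parameters d: an exact Gibbs draw from the conjugate multivariate
   normal full conditional given delta and sigma.
4. sigma: a random-walk step on its conditional given the residuals.

Two interweaving moves repair the slow mixing of this centered
parameterization when the data are homogeneous (sigma near 0, exactly the
null-simulation regime): a *translation* move shifts each d_t together with
its random effects (residuals fixed, so the likelihood of the affected arms
drives d directly), and a *rescale* move multiplies sigma and all residuals
by a common factor.  Both are standard ancillarity–sufficiency style moves;
with them, 2 chains × 10,000 draws give effective sample sizes of several
hundred for every basic parameter and for sigma on the full 117-trial
network (split-Rhat ≤ 1.01), versus ESS ≈ 10–60 without.

Step sizes adapt in batches of 50 during burn-in toward ≈35% acceptance
and are frozen afterwards.  Chains are seeded from independent substreams;
runs are exactly reproducible.  `sigma_fixed = 0` selects a common-effect
variant (no random effects; d updated by Metropolis against the
likelihood) used by the closed-form Wald oracle checks, where the usual
centered sampler would be degenerate.

### Significance rule

A contrast is significant when its 95% interval excludes OR = 1.  The
default rule forms the interval as exp(mean ± z·SD) of the pooled log-OR
draws — the normal approximation matching the "OR with standard errors on
the log-odds scale" convention; an equal-tailed credible-interval rule is
available (`rule="credible"`).  On the near-Gaussian posteriors in this
problem the two rules rarely disagree.

### Diagnostics

Split-Rhat (PSRF) and bulk ESS per basic parameter and sigma via ArviZ.
The pipeline flags a replication when any PSRF exceeds 1.05, retries once
with doubled burn-in and draws, and excludes it (reported, never silently
dropped) if still flagged — silent inclusion would bias the error rate,
silent exclusion would hide instability.

## FWER pipeline (`mtcsim.pipeline`)

One skeleton is generated once and reused across replications — the design
is fixed, only responses vary (a per-replication regeneration flag exists
for sensitivity analysis).  For each replication the pipeline fits the MTC
model, counts significant contrasts x, and summarizes: frequencies f(x),
probabilities P(X = x) = f(x)/n, the family-wise rate P(X ≥ 1), the
expectation E[X], and the independent-binomial reference (m·α and
1−(1−α)^m for m = 66, α = 0.05).  Posterior means and SDs of every
contrast are cached per replication, so significance can be recounted at
any other level — e.g. the Bonferroni threshold α/m = 0.05/66 ≈ 0.0008 —
without refitting, and per-replication contrast tables are checkpointed to
disk when an output directory is given, allowing interrupted runs to
resume.

## Direct REML meta-analysis (`mtcsim.direct`)

For a focused two-treatment question (e.g. one drug versus its pooled
head-to-head comparators), each two-arm trial contributes a log odds ratio
with Woolf variance; when any 2×2 cell is zero, 0.5 is added to all four
cells of that study (the correction policy is a documented default — exact
methods are out of scope).  Double-zero tables are excluded with a
warning.  The random-effects model y_i ~ N(θ, v_i + τ²) is fitted by REML:
Fisher scoring on the restricted likelihood from a DerSimonian–Laird
start, with step-halving so the restricted likelihood never decreases
(plain scoring can oscillate around small interior optima or the τ² = 0
boundary), floored at zero and converged at 1e-8.  Tests verify the
iterate against a dense grid-search maximizer to 1e-4.

## Problem sizes used in the test suite

The full-scale study is 1000 replications; the package's desk-scale runs
use 100 replications of the default network with a 2-chain,
2,500-burn-in / 5,000-draw sampler per replication, which puts a Monte
Carlo standard error of ≈ 0.045 on P(X ≥ 1) and ≈ 0.25 on E[X] and keeps
a full run in minutes on one core.  Calibration properties use smaller
networks: per-comparison type-I error on a 2-treatment network
(20 trials × 100/arm, 500 replications), parameter recovery of a planted
d = 0.5 (10 trials × 200/arm, 100 replications).  The 1000-replication
run is available through the CLI (`mtcsim simulate --reps 1000`).

## Known limitations

- The emulated topology is uniform over pairs; the original network's
  non-uniform multiplicities could shift P(X ≥ 1) and E[X] somewhat.
- The sampler is random-walk based; for networks far larger than ~100
  trials a gradient-based sampler would scale better.
- Only binary outcomes and the consistency (no inconsistency/node-split)
  model are implemented; informative priors and meta-regression are out
  of scope.
- The credible-interval rule shares draws with the point estimates; very
  short runs can make its tail quantiles noisy.
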