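# Methods

## Data model

A recruitment sample is a forest: seeds at wave 0, each recruit at its
recruiter's wave + 1. Waves and seed assignments are always recomputed from
the recruiter linkage and cross-checked against any wave/seed columns
present in a file; cycles, dangling recruiter references and wave
disagreements are hard errors. Seeds are excluded from every estimate (they
are purposively selected and carry no sampling probability), but a
seed-excluded view keeps each recruit's *recruiter* traits visible, because
wave-1 recruits' transitions originate at seeds and the transition matrix
needs the recruiter side of every pair.

Depth restriction keeps records with wave ≤ d (seeds retained
structurally). Records missing the analyzed trait are dropped for that
trait's estimate only, so denominators vary by trait.

## Estimators

**Sample proportion (SP).** Per-category count over the non-missing count,
with a Wilson score interval (statsmodels) recorded as the SP-specific
interval; the chain bootstrap below is also available for SP for
comparability.

**Degrees.** All weighted estimators use the self-reported network size
d_i ≥ 1. Missing or zero degrees are handled by a declared policy; the
default imputes the overall median of the positive reported degrees and
flags the imputation count in the result metadata (deterministic and
robust; the alternative `drop` policy removes the record from weighted
analyses). If no positive degree exists at all, weighted estimation refuses
to run and directs the user to SP.

**RDS-II.** θ̂_A = Σ_{i∈A} d_i⁻¹ / Σ_i d_i⁻¹. Equal degrees make it
collapse to SP exactly; a category with larger harmonic mean degree is
down-weighted relative to SP.

**Transition matrix and RDS-I.** Every recruit contributes one
(recruiter-category → recruit-category) pair with both sides observed.
Optional reciprocity smoothing symmetrizes off-diagonal counts,
t′_XY = t′_YX = (t_XY + t_YX)/2, before row-normalization (on by default,
selectable off; raw counts are always kept on the object). Rows for
categories that recruited nobody become uniform with a logged warning,
which keeps shallow depth-restricted subsets irreducible. The equilibrium
is found by power iteration from the uniform vector (tolerance 1e-12, cap
10,000 iterations). Reducibility is detected by strong connectivity of the
positivity pattern; a reducible matrix stores the observed recruit-category
mixture in the equilibrium slot, flagged `fallback` (the stationary
distribution is not unique, and the recruit mixture is the only
seed-influenced distribution guaranteed to be available to the operation).
RDS-I itself refuses reducible matrices with a diagnostic rather than
silently using the fallback. The K-category form is used throughout:
θ̂_X ∝ e_X / D̂_X with D̂_X = n_X / Σ_{i∈X} d_i⁻¹; no repeated binary
splits.

**RDS-SS.** Successive sampling: n units drawn one at a time, each draw
probability-proportional-to-degree among units not yet drawn, from a
population of assumed size N. Inclusion probabilities per degree class are
computed with a deterministic *expected-depletion* recursion: track the
expected remaining count R_d(k) per degree class, remove the expected
fractional draw p_d(k) = d·R_d(k)/Σ_d d·R_d(k) at each of the n steps
(clipped so a class cannot go negative), and set
π(d) = Σ_k p_d(k)/N_d. The self-consistent loop alternates (i) scaling the
current unit weights into an estimated population degree composition over
the grid of unique observed degrees, (ii) running the recursion, (iii)
resetting weights to 1/π(d_i); convergence when the largest relative
weight change falls below 1e-5, cap 75 outer iterations (non-convergence is
an error reporting the last relative change). Estimates are weight shares
as in RDS-II. As N → ∞ the recursion gives π(d) ∝ d and RDS-SS reproduces
RDS-II (verified to 1e-3 at sampling fraction ≤ 1e-4); at realistic
sampling fractions high-degree classes are depleted and the estimate moves
from RDS-II toward SP. The recursion is validated against brute-force
Monte-Carlo successive sampling on a 30-unit population (20,000 draws,
agreement within 3 Monte-Carlo SEs).

For unknown MSM population sizes, `ss_population_bracket` implements the
1–3%-of-adult-men convention and the estimator is intended to be run at
both endpoints; the assumed N is recorded on every result.

## Chain bootstrap

All estimators share one resampling scheme (comparability across estimators
is the point of the package): each replicate regenerates a pseudo-chain of
the observed analysis-set size, starting from a uniformly drawn recruit and
repeatedly drawing the next individual uniformly *with replacement* from
recruits whose recruiter belonged to the current individual's category
(uniform over all recruits when that category recruited nobody; recruits
whose recruiter's trait is unobserved belong to no pool and are reachable
only through that fallback). The chosen estimator is evaluated on each
replicate — RDS-I builds its transition matrix from the replicate's
consecutive pairs, which are by construction draws from the recruiter-
conditional rows — and the 95% interval is the 2.5/97.5 percentile of the
replicate distribution (percentile, not BCa; no bias-correction is
implied by the scheme). The point estimate is always the full-sample
estimate. Default 1,000 iterations. Replicates are generated once as an
index matrix and all estimators are evaluated on the same replicates in
vectorized batch passes; batched RDS-I equilibria use damped power
iteration on (I + S)/2, which shares S's stationary distribution and is
aperiodic, so occasional periodic replicate matrices still converge.
Estimator failures (e.g. RDS-SS non-convergence) are tolerated up to 10% of
replicates and excluded from the percentiles; beyond that the bootstrap
errors with a failure census.

## Simulator

`generate_population` draws N units with independent categorical traits and
zero-truncated negative-binomial degrees (dispersion parameter 2 by
default, giving the heavy right tail typical of self-reported network
sizes). A unit's mean degree is the geometric mean of the per-category
means over the traits that declare degree effects — exact for the
single-trait scenarios used in all quantitative checks. The default
scenario mirrors the package's reference study design: N = 34,678 (the 1%
population-size assumption), a binary HIV-like trait with prevalence 0.152,
mean degrees 38 (negative) vs 52 (positive) and homophily 0.10;
`study_config()` adds country of birth (prevalence 0.846, homophily 0.35),
three-category sexual identity (0.55/0.429/0.021, homophily 0.30) and
condom use (0.5/0.5, homophily 0.05). 14 seeds, 4 coupons each, 3 per
recruit, coupon return probability 0.36, target enrolment 1,376 including
seeds, 31-wave cap.

`simulate_recruitment` processes coupons in enrolment order. Each processed
coupon returns independently with the configured probability; a returned
coupon recruits an unsampled peer chosen **probability-proportional-to-
degree** — a returned coupon traverses a random network tie, whose endpoint
is degree-biased; uniform choice would make inverse-degree weighting itself
biased — restricted to the recruiter's own category with probability equal
to each trait's homophily strength. Sampling is strictly without
replacement from the finite population. Seeds are drawn
degree-proportionally by default (seeds are well-networked by design),
optionally stratified by trait or introduced in staggered batches.
Reported degree equals true degree unless a multiplicative log-normal
reporting error is configured; recruitment eligibility always uses true
degree, so reporting-error bias experiments are possible. `coupons_issued`
counts coupons whose return was resolved before enrolment stopped, so the
realized return rate matches the configured probability the way a study's
distributed-coupon count relates to its observed return rate. An optional
explicit-network mode builds a (category-assortative) configuration-model
graph and recruits uniformly among unsampled neighbours; it is a
sensitivity tool, supports assortativity on one trait only, and is not used
by the quantitative checks.

What the simulator does *not* emulate: correlated traits, degree-dependent
coupon compliance, differential eligibility or dropout, temporal dynamics,
and any claim about the real study population's network topology. Passing
parameter-recovery tests therefore show the estimators behave correctly
*under the model they assume* (degree-proportional referral, accurate
degree reports), not that they are unbiased on real data.

## Diagnostics

Homophily is the piecewise index
H = (S_AA − e_A)/(1 − e_A) if S_AA ≥ e_A, else (S_AA − e_A)/e_A — bounded
in [−1, 1], zero at neutral recruitment, undefined (NaN, flagged) when
e_A ∈ {0, 1}; reported per category, with the analysis category's value
playing the per-variable role. Convergence depth is the smallest w with
max|s·Sʷ − e| ≤ 0.02 (the conventional equilibrium criterion; configurable),
where s defaults to the observed seeds' trait mixture, since convergence is
about seed bias. Mean network size per subgroup is the arithmetic mean of
effective degrees at the current depth cut. Note that degree-proportional
recruitment inflates *sampled* mean degrees above the population means
(E[d²]/E[d] > E[d]); the group ordering and ratio are preserved, which is
what the diagnostics are read for, and recovery of the configured
population means is checked on the generated population itself.

## Comparison framework

The grid runs restrict-to-depth → exclude-seeds → estimate for every
(trait, method, depth) cell; failures are recorded per cell, never fatal.
Default depth set {5, 10, 15, 20, full}. Each trait declares a focal
category (the "positive"/last declared category by default) and the CV —
sample standard deviation (ddof = 1, appropriate for 3–5-value series) over
mean — is computed on the focal series: across depths per method (SP
included) and across the three RDS methods per depth (SP excluded). CV of a
zero-mean or single-value series is NaN, flagged, never an exception.
Reports are deterministic CSV + text.

## Study sizes

The coverage study uses 50 independent replicates of the default scenario
with 1,000-iteration bootstraps (≈3 minutes on one core), with a ≥85%
pass line for a nominal 95% interval at that replicate count; the CV-pattern
study uses 50 replicates and compares medians of the across-methods CV at
depth ≤5 vs ≤20 and of the across-depths CV of SP vs each RDS estimator.
The Monte-Carlo oracle for the successive-sampling recursion uses 20,000
draws of 10 units from a 30-unit population with degrees {1, 2, 5}.

## Known limitations

* The chain bootstrap is known to be anti-conservative in adverse designs
  (strong homophily, few long chains); observed coverage ≈96% here reflects
  the low-homophily reference scenario.
* RDS-I's uniform-row repair for non-recruiting categories is a pragmatic
  regularization; with very sparse categories the equilibrium is driven by
  that prior.
* The multi-trait degree model composes geometrically and assumes trait
  independence; it is not intended for studies where degree effects
  interact.
* Continuous traits, regression weighting and the model-assisted estimator
  are out of scope.
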