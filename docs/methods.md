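# Methods

## The task and the generative stimulus model

The package models a sequential orientation-categorisation ("weather
prediction") task.  On each trial a sequence of up to 40 oriented stimuli is
drawn i.i.d. from one of two von Mises distributions over orientation
(period pi), with means at -45 and +45 degrees from vertical and
concentration kappa = 0.5 — a strongly overlapping discrimination in which
single samples are ambiguous and accuracy comes from accumulation.  A trial
bank contains 100 pre-defined trials, half from each category; the same bank
is reused across all task contexts, mirroring the repeated-trials design of
the experiments this class of models is built for.

The evidence carried by an orientation theta is the log-probability
difference of the two categories,

    ell(theta) = kappa * [cos(2(theta - mu1)) - cos(2(theta - mu2))],

which for the default categories reduces to -2 kappa sin(2 theta) and is
bounded in [-2 kappa, +2 kappa].  The additive normalisation constant of the
log-densities cancels in the difference and is dropped.

## The suboptimal observer

The ideal observer sums ell over the samples shown and chooses category 1
iff the total exceeds zero (ties go to category 2).  The suboptimal observer
departs from this in four ways:

* **Inference noise** `sigma`: i.i.d. zero-mean Gaussian noise added to each
  evidence sample at the accumulation stage (not to the orientation
  estimate; no sensory-noise parameter exists in the model).
* **Leak / temporal bias** `alpha`: the accumulator follows
  `z_N = alpha * z_{N-1} + (ell_N + eps_N)`, so the weight on sample n at
  length N is `alpha^(N-n)`.  `alpha > 1` produces primacy, `alpha < 1`
  recency.  The recursion re-applies the weighting as the sequence grows —
  the only reading consistent with online stopping.
* **Collapsing decision bound** `Lambda_n = n (a + b exp(-n / lambda))`:
  the per-sample bound decays from `a + b` toward the asymptote `a` with
  time constant `lambda` (in samples), approximating a constant bound on
  the probability of a correct response.  The decision is made at the first
  sample where `|z_n| > Lambda_n`; if no crossing occurs by the last sample
  the task forces a response there with the sign rule.  `lambda` is the
  parameter observers adjust between target-performance conditions, so it
  may be given per condition.
* **Non-decision lag** `mu_U`, `sigma_U` (sample units): the overt response
  trails the covert decision by a rounded Gaussian lag.  In the simulator
  negative lags are clipped to zero and responses are capped at sample 40;
  in the likelihood the decision-sample distribution is convolved with a
  Gaussian kernel discretised at integer offsets within 4 SD (renormalised),
  with shifted-out mass accumulating at the first/last sample.  The
  convolution admits small negative lags that the simulator forbids; with
  the default `mu_U >= 0.5` the discrepancy is negligible and is accepted
  as the standard smoothing form.

Response bias (`bias`, added to the decision variable before the sign rule)
and a lapse rate (`lapse`, probability of a stimulus-independent random
choice) exist in the full model but are fixed at 0 and 0.001 by default:
the knock-out analysis this model family underwent removes them.  The final
Type-I model therefore has seven free parameters for joint what+when
fitting (`sigma, alpha, a, b, lambda, mu_U, sigma_U`) and two
(`sigma, alpha`) for choice-only fitting.

## Confidence (Type-II) layer

Confidence ratings 1-4 are read out from a second accumulator `z_c` against
three criteria sharing the collapsing-bound shape (`a_c`, `b_c`) with
separate decay constants `lambda_1 <= lambda_2 <= lambda_3`, evaluated at
the trial's final sample index; the rating depends only on `|z_c|`.  The
ordering is enforced by construction when fitting (increments
`lambda_1, delta_2 >= 0, delta_3 >= 0`), which removes the pathological
regime where higher confidence would demand less evidence.  The criteria
share `a_c, b_c` with each other but not with the Type-I bound; whether
they should also share the Type-I values is left open by the model family,
and independence is the more conservative default.

Architecture variants (`ModelVariant`) span the model-comparison space:

* `covert_bound`: none / absorbing / reflexive.  With an absorbing covert
  bound the Type-I accumulator freezes at the first crossing even though
  stimuli keep arriving (forced-viewing replay trials); a reflexive bound
  folds the overshoot back inside instead.
* `type2_coupling`: `same_z` (the ideal Type-II observer, one accumulator),
  `independent` (separate noise draws), `partial` (shared noisy evidence
  stream plus additional Type-II noise `sigma_c` and its own leak
  `alpha_c`).  The default — the winning architecture — is partial.
* `type2_noise_mode`: the extra Type-II noise enters per sample or as a
  single draw per trial.
* `type2_bound`: none / the Type-I bound / an independently parameterised
  bound on Type-II accumulation.  The default is none: Type-II evidence
  accumulates over all presented samples.

## Likelihoods

There is no closed form for the first-passage time of the bounded leaky
accumulator, so trial likelihoods are simulation-based, with an explicit
seed and one frozen noise matrix per fit (common random numbers) so that
the objective is a deterministic function of the parameters.

`response_pmf_mc` estimates f(n) — the probability of deciding with each
choice at each sample — as raw crossing frequencies over `n_mc` noise paths
(default 1000).  The fitting path (`nll_stopping`) instead uses a
Rao-Blackwellised sequential estimator of the same distribution: at each
step the exact Gaussian probability of crossing either bound given the
current accumulator state is accrued, and paths continue with a
truncated-normal draw from the no-crossing region (inverse-CDF on frozen
uniforms).  The two estimators target the same quantity; the sequential one
is smooth in the parameters and has far lower variance, which
derivative-free optimisation requires — with raw counts the objective is
piecewise constant and bound parameters cannot be recovered at realistic
budgets.  Mass is conserved to 1e-9 throughout; censored (no-crossing) mass
is assigned to a forced response at the last sample, matching the
simulator.  With `sigma = 0` the accumulation is deterministic and a single
noiseless path is used.

Fixed-length unbounded (replay-style) choices admit an analytic form:
`z_T` is Gaussian with mean `sum ell_n v_n` and SD `sigma sqrt(sum v_n^2)`,
so P(choice 1) = `lapse/2 + (1 - lapse) Phi(mean/SD)`.  This is used as the
fast path for Type-I-only replay fits and as the oracle against which the
Monte-Carlo estimator is tested.

Joint replay likelihoods (choice x rating, 8 cells) are Monte-Carlo
frequencies under the variant's coupling, lapse-mixed over cells
(`lapse/8`); lapse affects choices, not the timing axis.  Probabilities are
floored at `lapse / (2*40*4)` before logs — a floor consistent with the
lapse semantics that keeps impossible responses finitely costly.

## Fitting

The named optimiser of the original fitting pipeline is replaced, per the
module contract, by any robust derivative-free bounded search.  Two are
provided: multi-start Nelder-Mead in a unit-cube reparameterisation of the
hard bounds (cheap; adequate for 1-3 parameter problems) and a small
differential-evolution search initialised inside the plausible bounds with
a Nelder-Mead polish (default for the 7-parameter stopping fits, where
Nelder-Mead alone stalls).  Plausible bounds (defaults:
sigma [0.1, 4], alpha [0.5, 1.5], a [0.05, 2], b [0, 5], lambda [0.5, 20],
mu_U [0, 6], sigma_U [0.1, 4]; all config-overridable) seed the search;
hard bounds constrain it.

Parameter recovery — the pipeline's validation — simulates 300 stopping
trials per synthetic observer, refits, and reports Spearman rank
correlations between generating and recovered values.  Two designs are
provided.  The default `joint` design covers the three target conditions
(100 trials each) and fits shared suboptimalities with one bound decay per
condition, mirroring the final fitting structure; responding early under
the fast-collapsing bound and late under the slow one is what identifies
the bound shape, and the three decays pool into one `lam` correlation.
The `single` design simulates one condition (its decay drawn uniformly
over the generating range — the sorted per-condition draws are order
statistics that would compress the spread the correlation is computed
over) and fits the seven-parameter model; it is roughly three times
cheaper per observer and is what the test suite runs at 60 observers.
Recovery fits search within the plausible bounds: at 300 trials a
fast-responding observer's data cannot distinguish its true parameters
from remote basins (e.g. extreme primacy plus a slowly collapsing bound),
and the plausible region is precisely the instrument that excludes them.

Recovery quality is parameter-dependent.  Inference noise, the bound-decay
constant, the bound scale and both non-decision parameters rank-recover
strongly at this scale.  The leak `alpha` and the bound asymptote `a` do
not: at 300 trials their likelihood profiles are nearly flat for observers
who respond within the first few samples (the asymptote only matters late
in the sequence, and the leak trades off against the bound shape), and
enlarging the fit budget several-fold does not reduce the scatter — it is
an identifiability limit of the design at this trial count, not an
optimiser artefact.  Users who need those two parameters should use the
joint design with more trials per observer.

## Model comparison

BIC (`2 nll + k ln n`) per subject, converted to log model evidence as
-BIC/2, feeds random-effects group Bayesian model selection: the standard
variational Dirichlet scheme over model frequencies, iterating
responsibilities `u_nk ∝ exp(lme_nk + psi(alpha_k) - psi(sum alpha))` and
counts `alpha = 1 + sum_n u_n`, with exceedance probabilities computed by
Monte-Carlo over the Dirichlet posterior.  The knock-out procedure fixes
one parameter at a time to its neutral value (bias 0, lapse 0.001, alpha 1,
b 0) and lets group selection decide whether the restriction is favoured.

Five-fold cross-validation assigns trials (not blocks) to folds, seeded and
stratified by condition, and reports held-out log-likelihood per trial.
The covert-bound comparison fits the bound parameters on training folds
with the accumulation suboptimalities fixed, scores choices for the Type-I
bound question and the joint choice-confidence likelihood for the Type-II
bound questions, and calls a bound "favoured" when it improves held-out
log-likelihood by more than 0.01 per trial.

## Measurement layer

* `dprime`: equal-variance SDT sensitivity with a log-linear correction
  (add 0.5 to extreme cells' counts) so perfect performance stays finite.
* `meta_dprime`: maximum-likelihood meta-d' — the Type-I sensitivity an
  ideal SDT observer would need to reproduce the confidence-conditional
  accuracy, holding the relative Type-I criterion fixed and fitting one
  meta-d' with three ordered Type-II criteria per response side, by
  Nelder-Mead on the multinomial likelihood of the rating counts
  (conditional on response).  Counts are smoothed by 0.5/n_ratings per
  cell.  A single meta-d' (not response-specific) is estimated; ratings are
  never pooled for this estimate.  meta-d'/d' is Type-II efficiency.
* `optimal_lambda`: simulates stopping accuracy over a grid of bound
  decays (default 25 points, geometric over [0.3, 30], 1000 noise paths per
  trial, one frozen noise matrix across the grid), enforces monotone
  accuracy by a running maximum, and interpolates the decay achieving a
  target proportion correct.  Unreachable targets return the decay at
  maximum performance, flagged — mirroring the fallback needed when some
  observers cannot reach the strictest target.
* `bound_efficiency`: `(lam_fit_85 - lam_fit_70) / (lam*_85 - lam*_70)` —
  the observer's actual bound adjustment between the 70% and 85% targets
  over the adjustment that would have hit them; the 90% condition is
  excluded because the target is often unreachable.  The measure is
  invariant to an absolute bias in bound placement.
* `orthogonal_fit`: total-least-squares line (first principal axis of the
  centred cloud) with a non-parametric bootstrap one-sided p-value on the
  slope sign.

## What the synthetic data do and do not emulate

Synthetic observers are parameter sets drawn uniformly from ranges chosen
to produce realistic behaviour in this stimulus regime: above-chance
accuracy (roughly 0.65-0.9), median response samples spread over the
sequence rather than piling at either end, stopping-condition decays
ordered `lambda_70 <= lambda_85 <= lambda_90`, and confidence ratings that
span the scale.  The generator reproduces the protocol's structure — the
three tasks, two blocks per stopping condition, three free repetitions,
and the Less/Same/More rule (min-2 floored at 1 / median / max+4 capped at
40) — but not stimulus rendering, timing in seconds, practice blocks,
feedback or points, pupillometry, or any within-session non-stationarity
(fatigue, learning).  Passing tests therefore demonstrate that the
estimation and comparison machinery is correct and well calibrated under
the model's own assumptions, not that the model describes any particular
human dataset.

## Numerical choices and degenerate inputs

* Ties: `z = 0` maps to choice 2, exactly as the sign rule is stated.
* Orientations are radians internally; the trial-bank CSV stores degrees.
* Non-decision kernels with SD far below the sample grid degrade to a
  delta at `round(mu_U)`.
* The sequential likelihood terminates early once all surviving path
  weight falls below 1e-12 (the abandoned mass is below the conservation
  tolerance).
* Problem sizes in the test-suite (n_mc 64-1000, 20 recovery observers,
  two observers in the cross-validation comparison) are the package's
  scaled study conditions; they were chosen so the full validation runs on
  a single CPU in minutes while keeping each check statistically decisive.

## Known limitations

* The likelihood treats the 100 bank trials as the support of the data;
  behaviour referencing unknown trials is rejected rather than marginalised.
* meta-d' assumes equal-variance SDT and a stable criterion; hierarchical
  or response-specific variants are out of scope.
* The reflexive covert bound is provided as a variant flag and simulator
  path only; the default analysis pipeline uses the absorbing bound.
* Type-II noise at the accumulation stage and at the output stage are not
  distinguishable in this design; only the accumulation-stage form is
  implemented.
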