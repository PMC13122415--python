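# Methods

`intervalconsensus` estimates a group's latent consensus *interval* per item
from continuous bounded interval responses, in the tradition of cultural
consensus theory (CCT): responses are aggregated while each respondent is
weighted by an inferred proficiency.

## The link function

A response interval `[lower, upper]` on the unit scale is equivalent to a
three-part composition on the simplex,

    m = (lower, upper - lower, 1 - upper),

i.e. (left gap, width, right gap). An isometric log-ratio (ILR) transform
maps the composition to an unbounded plane:

    loc = k1 * ln(x1 / x3),          k1 = 1/sqrt(2)
    wid = k2 * ln(x2 / sqrt(x1*x3)), k2 = sqrt(2/3)

`loc` compares the gaps left and right of the interval (0 = centred;
positive = shifted right). `wid` compares the interval's width to the
geometric mean of the two gaps; because of that geometric mean, a fixed
bounded width transforms to a larger |wid| near the scale limits than at the
centre, which compensates for the compression imposed by the bounded scale.
The constants are the orthonormal ILR basis for a three-part composition;
they are exposed as arguments of `ilr`/`ilr_inverse` since any positive
constants give the same qualitative geometry.

Zero components (boundary-touching, point, or full-scale responses) make the
log-ratios undefined, so a padding constant `c` (default 0.01) is added to
all three parts and renormalised before the transform, and removed after the
inverse transform. Padding is global — the same `c` for every response —
which preserves ratios of padded components *across* responses; it is
skipped automatically when no response touches a boundary. The whole chain
is numerically invertible to about 1e-8 over the full unit square, including
boundary cases.

## The observation model

Respondent `i` appraises item `j`'s latent consensus `T_j = (T_loc, T_wid)`
(on the ILR scale) with bivariate-normal error, then applies person-level
response biases:

    mean  = (a_i * T_loc_j + b_loc_i,  T_wid_j + b_wid_i)
    SDs   = (a_i / (E_loc_i * lam_loc_j),  1 / (E_wid_i * lam_wid_j))
    corr  = rho_j

* `E_i` (proficiency, person) and `lam_j` (discernibility, item) are
  precision-type parameters: doubling either halves the error SD. The
  reciprocal-product form `sd = 1/(E*lam)` is the minimal inversion of the
  older CCT convention in which SDs multiply; it is isolated in
  `response_cov` so alternatives can be swapped.
* `a_i > 0` is a multiplicative extremity bias acting on the location
  dimension only — the width origin is not a meaningful anchor for scaling,
  since the bounded width that corresponds to `wid = 0` depends on the
  interval's location. Because the appraisal is consensus-plus-error, `a_i`
  scales the error SD as well as the mean.
* `b_i` are additive shifting biases per dimension.
* `rho_j` is an item-level residual correlation between the two error
  dimensions.

Any of `a`, `b_loc`, `b_wid` can be dropped (model variants); dropping a
parameter removes its likelihood contribution and its hyperprior, and the
reduced likelihood coincides exactly with the full likelihood at the
constrained values (a = 1, b = 0).

## Priors and identifiability

The consensus prior is specified on the *bounded* scale: the interval width
`w_j ~ Beta(2, 4)` (mean 1/3, mode 1/4 — full-scale consensus intervals are
a priori implausible, though full-scale *responses* remain possible) and an
auxiliary location multiplier `lamstar_j ~ Beta(1, 1)` with
`lower = lamstar * (1 - w)`. The induced composition is mapped through the
ILR to give `T_j`; sampling happens in the bounded parameterisation, so no
explicit Jacobian for the ILR is needed. A uniform Dirichlet prior directly
on the simplex is provided as a documented alternative
(`consensus_prior_dirichlet_logpdf`).

Hierarchical priors: bivariate log-normal on `(E_loc, E_wid)` with free mean
`mu_E`, log-normal on `lam` with the mean fixed at 0 (this anchors the
overall precision scale to the proficiencies), and
`rho = 2*Beta(s, s) - 1` with `s = 2` (mild shrinkage toward 0).
Identifiability of the bias parameters is enforced by *hard* constraints:
the shifting biases and the log-discernibilities sum to zero exactly, and
the scaling biases satisfy `mean(a) = 1` exactly via a softmax pushforward
(`a = N * softmax(u)` with `u` on the centred subspace). Hard constraints
give exact finite-sample identification; the data-generating draws use the
same pushforwards, so the generative law and the fitted prior agree.
By default the correlations between the two dimensions of log-proficiency
and log-discernibility are fixed at 0 (independent univariate priors);
`estimate_correlations=True` adds them with scaled-Beta(2,2) priors.

Hyperpriors: `N(0,1)` on the components of `mu_E` and half-normal(1) on all
scale parameters — weakly informative on the unbounded scale.

## Estimation

The posterior is sampled with a dynamic-trajectory Hamiltonian Monte Carlo
sampler (NUTS-type multinomial trajectory sampling, generalised U-turn
criterion, dual-averaging step-size adaptation toward a target acceptance
statistic, windowed diagonal mass-matrix adaptation, divergence threshold
1000 on the energy error). The log-posterior and its analytic gradient are
implemented twice — a readable numpy reference and a numba-compiled kernel —
and the two are asserted identical in the test-suite; gradients are checked
against finite differences.

Parameterisation choices that matter for sampling:

* Sum-to-zero blocks use the orthonormal Helmert basis (J-1 or N-1 free
  coordinates), so the constrained prior is an isotropic standard normal.
* Person/item effects are non-centred (innovations times scale).
* Between trajectories an extra posterior-invariant kernel decorrelates the
  hierarchy: a slice-sampling move along each scale block's funnel diagonal
  (`log sigma += t`, innovations scaled by `exp(-alpha*t)` with a random
  compromise angle and the exact Jacobian), a non-centred slice update of
  the scaling-bias scale, a single-site Metropolis scan with prior
  proposals over each person's joint (scaling-bias, location-proficiency)
  innovations — these two parameters form a weakly identified ridge per
  person — an exact conjugate Gibbs draw of the shifting-bias innovations
  (their full conditional is Gaussian: per-person 2x2 data precisions plus
  the identity in Helmert coordinates), and an ancillarity–sufficiency
  interweaving sweep that redraws each scale (and `mu_E`) from its exact
  conditional in the centred representation. Without these moves the scale
  hyperparameters (particularly `sigma_a`, whose posterior spans an order
  of magnitude) mix an order of magnitude more slowly; invariance of each
  component was checked by moment-matching long runs against plain HMC.
* Mass-matrix adaptation is pooled across chains: each chain adapts its own
  diagonal metric over the first 70% of warmup, the metrics are combined by
  element-wise geometric mean, and the remaining warmup re-tunes only the
  step size under the shared metric. With chain-specific metrics, a chain
  that spends its warmup in one region of a multi-regime posterior can
  adapt a metric that traps it there; a pooled metric makes the transition
  kernel common to all chains.

Defaults: 4 chains, 1,000 warmup + 500 kept draws per chain (2,000 total),
target acceptance 0.9, raised to 0.99 for designs with at most 500
responses (small and mid-sized designs are divergence-prone), initial
values uniform on (-0.5, 0.5) on the unconstrained scale, three
rejuvenation sweeps per iteration. Convergence is summarised by split
R-hat and effective sample size (arviz) over all stored parameters, plus
the divergence count.

Point estimates are posterior medians. Consensus summaries are computed
draw-wise: each draw of `T` is mapped through the inverse ILR and unpadding
to a bounded interval *first*, and quantiles are taken afterwards, so the
non-linear transform does not distort posterior uncertainty. The per-person
proficiency score standardises the posterior medians of `E_loc` and `E_wid`
across persons, averages them, and maps ranks to standard normal quantiles —
a robust diagnostic for flagging non-effortful responders.

## Baselines

The competitor aggregators transform every response with the same padded
ILR, take the componentwise mean or marginal median per item on the
unbounded scale, and back-transform. Medians use the midpoint convention
for even counts. Because the link is non-linear, the mean on the unbounded
scale is not the mean of the observed bounds; the tests document this.

## Simulation study

Datasets are generated from the model itself. The consensus-generating
normal on the unbounded scale is derived from three anchor intervals rather
than specified numerically: the mean is the ILR image of a "typical"
interval ([0.4, 0.6]), and the per-dimension SD is set so that the ILR
image of an extreme anchor ([0.9, 0.95] for location, [0.1, 0.9] for width)
lies four standard deviations from the mean. With the default anchors this
gives mean (0, -0.57) and SDs (0.51, 0.57). The derivation procedure, not
the specific anchors, is the contract; all anchors are configurable.

Bias and precision hyperparameters for generation default to
`sigma_E = sigma_lam = (0.5, 0.5)`, `sigma_a = 0.2`,
`sigma_b = (0.25, 0.25)`, `omega = 0`, chosen to produce plausible response
interval distributions (unimodal widths bounded away from full scale,
locations spanning the scale without piling on the boundaries).

The full condition grid crosses {10, 50, 100, 200} respondents with
{5, 10, 20, 40} items; every repetition draws fresh true parameters with a
seed that is a deterministic function of (base seed, N, J, repetition), so
any subset of the study can be reproduced in isolation. Performance
measures: absolute bias and MSE of the latent consensus (per dimension and
jointly, the joint value averaging the two dimensions' error components over
items and repetitions), and the average per-repetition Pearson correlation
between estimates and truths per parameter family. Monte Carlo standard
errors come from a seeded bootstrap over repetitions; ICM-vs-baseline
comparisons bootstrap the paired per-repetition differences.

### Problem sizes used in the shipped checks

The automated checks run desk-scale versions of the study: parameter
recovery at 50 respondents x 10 items with four repetitions at the full
sampler settings; the baseline comparison and the sample-size trends at
(50, 10), (10, 10), (10, 5) and (10, 20) with 20 repetitions and light
sampler settings (2 chains, 250 warmup + 200 kept, one rejuvenation sweep —
posterior medians, which are all the study scores use, are stable at these
settings). `scripts/acceptance.py` repeats the single-condition study at
(50, 10) with 10 repetitions. The original-scale study (hundreds of
repetitions, 16 conditions) is available through `run_study` /
the `icm simstudy` command with a larger configuration; an incremental mode
(run batches until the MCSE of the primary measure meets a threshold) can
be emulated by increasing `reps` and re-running with the same base seed,
since per-repetition seeds are deterministic.

## What the generator does and does not emulate

The synthetic data follow the model's own assumptions: bivariate-normal
appraisal errors on the ILR scale, log-normal person/item precision
parameters, exact identifiability centring. Real interval data violate
these in known ways — slider end-effects and digit preference, respondents
who anchor on round numbers, mixtures of qualitatively different response
strategies, and item clusters sharing more than one consensus. Passing the
shipped checks therefore demonstrates correct self-consistent estimation
(the estimator recovers the process that generated the data, and beats
unweighted aggregation when its assumptions hold); it does not certify
performance under misspecification.

## Numerical choices and degenerate inputs

* Simplex sums are validated to 1e-12 on construction; the full transform
  round trip is exact to 1e-8 (chains of about six elementary operations).
* `unpad` clamps components in [-1e-9, 0) to zero and rejects anything more
  negative as an inconsistent padding constant.
* Point responses (`lower == upper`) and full-scale responses (`[0, 1]`)
  are legal and handled by padding, never dropped.
* Raw bounds on a [0, 100] scale are rescaled at ingest (`scale_max=100`).
* Inputs where every response is identical trigger a warning (the
  proficiency scale is then unidentified) but still fit.
* Designs need at least 2 respondents and 2 items, each with at least one
  response; missing cells are simply absent likelihood terms.
* All randomness flows from one user-supplied seed through named
  `numpy.random.SeedSequence` substreams (per chain, per condition, per
  repetition).

## Known limitations

* Single-consensus model: no latent-class mixtures over multiple
  consensuses, no covariate regressions on person or item parameters.
* The amalgamation (stick-breaking) log-ratio link is not implemented as an
  alternative to the ILR.
* MCMC only; no variational or MAP shortcut.
* The marginal posterior of the scaling-bias scale `sigma_a` is typically
  wide (an order of magnitude) and, on some datasets, has both a
  "negligible scaling bias" region and a spread-out region. The extra
  kernels move between the regions every ~10 draws, but at the default
  2,000 total draws the between-chain variance of regime occupancy keeps
  the worst split R-hat around 1.01-1.03 on such datasets even with zero
  divergences. Analyses that need a tighter convergence certificate for the
  scale hyperparameters should increase the kept draws; the consensus and
  proficiency parameters themselves reach effective sample sizes in the
  thousands at the defaults.
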