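# Methods

`valconf` models two-alternative preference decisions with eye tracking:
choices and reaction times from a gaze-weighted evidence race, confidence
reports from generative readouts of that race, and valuation noise from an
efficient-coding account of the rating process. This note records the
models, the choices made where the design was open, the synthetic-data
conditions, and the limits of what the tests establish.

## The race model

Each trial runs two accumulators toward a common bound B. Item i's signal
is `S_i = g_i v_i + (1 - g_i) theta v_i`, where `v_i` is the item's value
readout (mean rating, on [0, 1]), `g_i` the trial's dwell share on item i,
and `theta <= 1` the attentional effort applied to the momentarily
non-fixated item. The relative signal `R_i = expit(tau (S_i - S_j))`
scales the drift `k R_i`; accumulation noise is Gaussian with standard
deviation `sigma` per root-second (the continuous-time reading, which is
the one under which the analytic first-passage expressions hold; a literal
per-step noise reading would tie sigma's units to the simulation step).
First-passage times are Wald / inverse Gaussian with mean `mu = B/(k R_i)`
and shape `lam = B^2/sigma^2`, and the likelihood of the observed
(choice, RT) is `f_winner(t) (1 - F_loser(t))`.

Numerical choices: B is fixed at 1 (only B/k and B/sigma are identified);
there is no non-decision time (the likelihood contains none; `GLAMModel`
exposes a fixed-offset hook, default 0); the survival function is
evaluated in log space with an `expm1` guard because the naive
`1 - F` cancels catastrophically when the loser is nearly sure to have
finished. The discrete-time simulator uses Euler-Maruyama steps (default
1-2 ms) with linear interpolation of the bound crossing and reads the
loser's location out at the interpolated crossing instant.

Subject-level fitting (`GLAMModel.fit`) is MAP with Nelder-Mead restarts
on (log k, log sigma, log tau, log(1 - theta)) and Hessian-derived
standard errors; full posterior sampling is available through the joint
model below. With a single trial configuration (identical values and
gaze on every trial) tau and theta are not identified — only their
composite R — so recovery tests always use trial sets spanning several
value-difference levels and dispersed gaze.

## Confidence readouts

*Heuristic (balance of evidence).* Confidence is `B - e_loser(t)`. Because
the loser's location is unobserved, the trial-level prediction uses the
expected location at the observed RT. The implemented default evaluates
`B - ((k R) t + phi(beta)/Phi(beta) sigma sqrt(t))`,
`beta = (B - (k R) t)/(sigma sqrt(t))`, exactly as the model is usually
written; note that the mean of a normal truncated below B carries the
Mills-ratio term with the opposite sign, so the textbook truncated mean
gives `B - ((k R) t - Mills sigma sqrt(t))`. Both variants are available
(`loser_mean_variant`), the default is the as-written form, and the test
suite pins the truncated variant to a Monte-Carlo oracle so the
discrepancy is documented rather than silently "fixed".

*Normative (probability correct).* Confidence is the probability the
choice was correct given decision time, choice class, process parameters
and the task's contextual statistics. `build_context_table` simulates
races across the session's trial configurations (uniform weight over the
observed (v_upper, v_lower, g_upper) triples) and tabulates the fraction
correct in (RT-quantile x loser-evidence) cells, add-one smoothed toward
the marginal accuracy (which also fills unreachable cells). A prediction
then marginalizes the unobserved loser evidence with its model-implied
density (normal, mean `(k R_loser) t`, variance `sigma^2 t`, truncated
below B and renormalized on the grid); the observed choice class selects
which accumulator is the loser. Defaults: 20 RT quantile bins, 25
evidence bins on `[B - 6 sigma sqrt(t_med), B)`, 1e5 simulations per
parameter set (scaled to 1e4-3e4 inside recovery studies). The table is
conditional on the process parameters, so trial-varying latents use a
small grid of tables (nearest node; `NormativePredictor`).

The readouts differ in exactly one scientifically relevant way: the
probability-correct readout inherits the accuracy benefit of higher
attentional effort (its mean output rises monotonically in theta), while
the balance-of-evidence readout is nearly flat in theta — opposing
effects of theta on the loser's drift and on the RT distribution cancel.

## Joint covariance model

Trial-wise `(c_n, theta_n, k_n)` — confidence report plus the two race
latents — are draws from a trivariate normal with mean
`(mu_c, mu_theta, mu_k)`, spreads `(sigma_c, sigma_theta, sigma_k)` and
correlations `(rho_ctheta, rho_ck, rho_ktheta)`. Priors: flat normals on
the means (the Normal(0, 1e-5) convention is read as a *precision* — the
variance reading would be a near-delta at zero and contradict the stated
uninformativeness), Uniform(0, 10) on spreads, Uniform(-1, 1) on
correlations subject to positive-definiteness.

Sampling interleaves three blocks per sweep: (i) latent residuals in a
non-centered parameterization (`(theta_n, k_n)` = conditional mean given
`c_n` plus Cholesky-scaled standard-normal residuals), refreshed by
independence proposals whose acceptance is the race-likelihood ratio;
(ii) adaptive Metropolis on the transformed hyperparameters with the
residuals fixed, so the race likelihood informs the correlations
directly; (iii) a centered Metropolis block on the shared linking
parameters given the current latents (trivariate-normal row likelihood),
after which the residuals are re-derived. The interweaving matters: a
purely centered Gibbs sampler (conjugate normal-inverse-Wishart) walks
into the degenerate rho -> 1 corner and stays there, and a purely
non-centered sampler mixes poorly over the spread parameters. The race's
(sigma, tau) are sampled in the chain by default ("joint" mode); a
two-stage "cut" mode freezes them at the first-stage MAP.

Single sessions of ~150 trials honestly identify `rho_ck` (reaction
times are informative about `k_n`) but leave `rho_ctheta` posteriors wide;
recovery studies therefore pool subjects (`JointModel.from_population`)
with shared linking structure and per-subject confidence location/scale,
which is also how the confidence scale-use differences between sessions
are absorbed.

Variant predictions (FH/VH/FN/VN) plug fixed subject-level (F) or
trial-conditional (V: the conditional posterior mean of `(theta_n, k_n)`
given `c_n` under the fitted linking) parameters into the heuristic (H)
or normative (N) readout, are mapped onto the confidence scale by
per-subject least squares, and are compared by PSIS-LOO and
bridge-sampling Bayes factors of the rescaling regression (conjugate
normal-inverse-gamma, so pointwise likelihoods are exact draws).

## Random-utility models

The baseline probit is `P(i over j) = Phi((v_i - v_j)/(sigma sqrt 2))`;
the attentional variant weights values by dwell shares `A_i` with the
unattended component discounted by theta, and reduces to the baseline
exactly at theta = 1. Reverse inference treats confidence as an observed
covariate: `theta_n = theta_base + beta_s^theta c_n` and
`k_n = k_base + beta_s^k c_n` with `k = 1/(sigma sqrt 2)`, subject slopes
drawn from population normals with flat (precision-convention) priors on
the means and Uniform(1e-10, 5) spreads. `k_n <= 0` is handled by
likelihood rejection rather than clipping. Confidence is not centered
before entering the links (a centering flag exists, default off).
Sampling is Metropolis-within-Gibbs: a 2-d base block, vectorized
per-subject slope blocks, conjugate population means and grid draws for
the population spreads; variant comparison uses PSIS-LOO on the Bernoulli
pointwise likelihoods.

## Efficient-coding valuation

Values live on (0, 1) under a Beta(omega) prior. Encoding uses the
uniformized scale `u = F(v0)` with constant noise `sigma_enc`; decoding
applies the prior quantile function `phi`. The decoded estimate's moments
are `E = v0 + phi'' sigma_enc^2` and `Var = (phi')^2 sigma_enc^2` with
`phi' = 1/p(v0)` and `phi'' = -p'(v0)/p(v0)^3` evaluated analytically
from the Beta density at F(v0). The bias term as commonly written omits
the 1/2 of the second-order delta method; a Monte-Carlo check in the test
suite shows the 1/2 variant (`delta_half=True`) is the one matching the
generative simulation, while the as-written form remains the default for
fidelity. Ratings add value-unspecific comparison noise `sigma_comp`
after decoding and are observed through a fixed logistic map g; the map's
slope defaults to 6 with midpoint 0.5 so that the unit value range covers
~90% of the physical scale (a unit slope would compress all ratings into
the middle quarter of the scale and make the designed 20% rating-
difference level unreachable; slope and midpoint are configuration
fields). Ratings at exactly 0 or 1 are clipped inward by 1e-4.

The rating model is fitted by Metropolis-within-Gibbs over the latent
item values (vectorized independent proposals — items are conditionally
independent) and a joint block on (omega, log sigma_enc, log sigma_comp).
Separating the two noise sources requires the value-dependence of the
across-phase rating variance, so single-rating datasets are rejected with
an explicit error. The choice stage is a probit on the decoded means with
summed decoding variances plus `sigma_comp^2` in the denominator,
attention-weighted exactly as in the random-utility model; the
confidence-linked hierarchical variant links theta, sigma_enc and
sigma_comp linearly to confidence with the stated uniform/flat priors
(theta_base in (-0.5, 1.5), beta_sigma_enc in (-0.2, 0.5), ...).

## Descriptive layer

Hierarchical logistic (consistency) and linear (confidence) regressions
on VD, Var and TV use varying subject intercepts and slopes, pooled
z-scored regressors (per-subject standardization available), flat priors
on population means and Uniform(0, 5) spreads. Reported "P-values" are
posterior tail masses. Effect-size contrasts are draw-wise differences of
population slope / population spread. Signature curves use equal-count
binning (bin sizes differ by at most one).

## Synthetic-data conditions

The generator emulates the behavioral design: 64 items rated twice,
trials balanced over four rating-difference levels (5/10/15/20% of the
scale, tolerance 1.25%) and over the screen position of the higher-rated
item, at most 240 trials, a 4 s response deadline (timeouts resampled —
the likelihood is uncensored, so censoring is deliberately avoided in the
generator), and fixation records that re-aggregate to the trial's dwell
share (bookkeeping, not a model of saccades).

Default study conditions, chosen once for realism: race k = 1.5,
sigma = 0.4, tau = 12, theta = 0.6 (mean RT ~0.9 s, RT coefficient of
variation ~0.4, consistency ~0.78 across the four VD levels); linking
means (0, 0.6, 1.5) with spreads (1.0, 0.25, 0.25) and correlations
(0.5, 0.7, 0.4); value prior Beta(1.2, 1.2) — the item set spans the
whole scale, so encoding noise is largest at both extremes, not only at
high values; sigma_enc = 0.05 > sigma_comp = 0.03; dwell shares
Beta(2, 2) whose mean shifts toward the currently higher-valued item by
1.2 x (value difference) (preferential looking). The endogenous-gaze
coupling and the fresh value draw at choice time
(`encoding_noise_in_choice`) are what produce the behavioral
dissociation: rating variability degrades consistency (the choice tracks
a fresh noisy decode while the consistency label tracks the rating mean)
but leaves confidence unaffected, while total value amplifies the
fixation-weighted signal difference under theta < 1 and raises
confidence. With an asymmetric value prior the summed value becomes a
proxy for encoding noise and masks the rating-variability effect — the
reason the symmetric prior is the default.

Recovery and model-recovery studies instead use `recovery_config()`:
exogenous gaze (Beta(1.3, 1.3), no value coupling), choices on the rating
means, tau = 8. Under those conditions the fitted race model is exactly
the data-generating process, which is what parameter-recovery claims
require; the behavioral-emulation defaults deliberately violate it.

Confidence reports are min-max rescaled within session from one of three
latent sources: the multivariate-normal confidence propensity itself
(`linking`, used when injected correlations must hold exactly in the
reports), or the heuristic/normative readout at the trial latents plus
reporting noise of 0.25 standard deviations.

What passing tests do not show about real data: the generator has no
serial dependencies, no non-decision time, no lapses, no within-trial
fixation dynamics, rating-scale use is unbounded by anchoring effects,
and every mechanism in the fitted models is present in the generator by
construction (except where a study deliberately breaks it, as above).
Recovery results certify the estimation machinery, not the truth of the
model for human data.

## Known limitations

- The joint model's correlation posteriors mix slowly (split R-hat for
  the spread/correlation block can exceed 1.05 at desk-scale chain
  lengths even when point summaries are stable); fidelity work should use
  longer chains via `MCMCConfig` or `fidelity_config()`.
- `NormativePredictor` discretizes the latent (theta, k) plane with
  nearest-node tables; very wide latent ranges would need a denser grid.
- The bridge-sampling estimator uses a moment-matched Gaussian proposal;
  strongly non-Gaussian posteriors would need a warped proposal, and the
  estimator reports failure rather than falling back silently.
- Timeout trials are resampled, not censored; a censored likelihood is an
  extension, not implemented.
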