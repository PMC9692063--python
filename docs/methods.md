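# Methods

## The retrieval model

`lv05abc` works with a deliberately minimal version of the Lewis & Vasishth
(2005; LV05) cue-based retrieval model, reduced to the two ingredients that
drive facilitatory interference in ungrammatical sentences: spreading
activation from retrieval cues and a noisy race between candidate chunks.

At the retrieval site (the verb in subject–verb agreement, the reflexive in
antecedent–reflexive dependencies) two chunks compete: the grammatical
*target* and a *distractor*.  Two cues probe memory: a *structural* cue
(subjecthood / c-command) that the target always matches, and a *number*
cue that only the distractor matches, and only in the *multiple-match*
condition.  Chunk activations are

    A_i = B_i + sum_j W_j * S_ji + eps_i,    eps_i ~ Normal(0, sigma),

the chunk with the highest realized activation is retrieved, and retrieval
takes `RT = F * exp(-f * A_winner)` seconds.  `F` is the latency factor
(per-participant reading-speed scale) and `f` the latency exponent.

Simplifications, all fixed in `LV05Config` and configurable:

* `S_ji = S_assoc = 1` for every matching cue–chunk pair — no fan effect;
  with two chunks and two cues a constant associative strength only sets
  the activation unit.
* `B_i = 0` — no base-level learning or decay.
* The cue weights satisfy `W_structural + W_number = W_total = 1`, so the
  cue-weighting ratio `CW = W_structural / W_number >= 1` is the single
  weighting degree of freedom; raising CW redistributes a fixed activation
  budget toward the structural cue rather than adding activation.
* `f = 1`, `sigma = 0.25` activation units by default.  Neither is
  estimated; `sigma` sets the scale of the race noise and therefore of the
  interference effect (about −16 ms at `LF = 0.2`, `CW = 1`).
* The race is decided by comparing activations at the moment of retrieval
  (activation-max rule).  Exact ties go to the target: for `sigma > 0` ties
  have probability zero, and a tie implies identical latencies anyway.
* The ACT-R retrieval threshold exists as an off-by-default flag that
  *flags* sub-threshold winners rather than dropping trials, so enabling it
  cannot silently change sample sizes.

Predicted summaries for a participant are the condition means over
`n_trials` simulated races: the interference effect
`effect_ms = mean(RT | multiple_match) − mean(RT | single_match)` (negative
= facilitation) and the grand mean RT, both in ms.  Each condition uses an
independent substream spawned deterministically from one root seed.  Two
structural facts are worth noting because the test-suite leans on them:
with `sigma = 0` the winner and its activation are identical across
conditions, so the effect is exactly zero; and `RT` is proportional to
`F`, so predicted summaries are exactly linear in the latency factor.

A deterministic oracle (`expected_latency_quadrature`) integrates
`F exp(-f x)` against the density of the maximum of the two activation
normals,
`p_max(x) = phi_t(x) Phi_d(x) + phi_d(x) Phi_t(x)`, with absolute
tolerance better than 1e-6 s.  The Monte-Carlo predictor is tested against
it at 3 MC standard errors.

## Synthetic data

Participants are drawn from the bivariate normal population

    (LF_j, CW_j) ~ N2( (mu_LF, mu_CW), [[sd_LF^2, rho sd_LF sd_CW],
                                        [rho sd_LF sd_CW, sd_CW^2]] ),

truncated to the model domain `{LF > 0, CW >= 1}` by rejection.  Rejection
keeps the population literally the stated bivariate normal restricted to
its support (no latent transformation), and an acceptance-rate guard
(error below 1%) makes pathological parameterizations loud instead of
silently biased.

Observed per-participant summaries are the model's Monte-Carlo predictions
plus independent Gaussian measurement noise (one shared SD per dataset,
default 5 ms in recovery studies) on both components — emulating shrunken
by-participant estimates from hierarchical regressions of raw reading
times, which carry roughly homogeneous posterior SEs within a study.  What
the generator does *not* emulate: trial-level reading-time skew, item
variance, the shrinkage step itself, or any dependence between a
participant's mean-RT error and effect error.  Passing recovery tests
therefore show that the estimator works when the data-generating process
matches the model plus homogeneous Gaussian summary noise, not that the
model is true of any real dataset.

The bundled 13-block fixture reproduces the structure of the published
facilitatory-interference datasets (11 agreement, 2 reflexive; participant
counts 40, 181, 32, 32, 32, 32, 28, 60, 60, 44, 60 and 40, 181; mean
effects from −60 to −4 ms).  For each block the mean latency factor is
calibrated by a Brent root find so that the quadrature-oracle effect at
(mu_LF, mu_CW) equals the published mean effect — no hand-tuned magic
numbers.  Block-level choices: mu_CW = 1.3 (agreement) vs 1.8 (reflexive),
reflecting near-equal weighting in agreement and a structural-cue bias in
reflexives; sd_CW = 0.4 / 0.6; sd_LF = 0.2 mu_LF; rho = −0.3; 15 ms
measurement noise.

## Hierarchical Gibbs ABC

For one dataset block with n participants the model has 2n + 5 parameters
— (LF_j, CW_j) per participant and (mu_LF, mu_CW, sigma_LF, sigma_CW,
rho) — plus one global nuisance offset `tbase` (ms).

**Summary statistic.**  The per-participant data are the pair (mean RT,
interference effect), not the effect alone.  The effect is proportional to
LF, so the effect alone leaves (LF, CW) unidentified along a ridge; the
mean reading time pins LF.  Because the retrieval model describes only the
retrieval stage, a shared offset `tbase` absorbs lexical/encoding/motor
time: the observed mean RT is compared against `simulated mean RT + tbase`.
`tbase` has a Normal(0, 50 ms) prior and is logged separately from the
2n + 5 model parameters.

**Approximate likelihood.**  The weight of a parameter pair is the average
over `n_sim = 24` forward simulations (each `n_trials_sim = 128` races per
condition) of the product of per-component Gaussian kernels
`exp(-d^2 / (2 delta^2))`.  Defaults `delta_rt = delta_eff = 5 ms`, equal
to the typical posterior SE of shrunken per-participant estimates.  The
tolerance acts as the effective measurement-noise scale of the ABC
likelihood: a tolerance well above the true summary SE provably washes out
population spread (with a 20-ms RT tolerance, a plausible sigma_LF of
0.03 s — about 15 ms of RT spread — is absorbed by the kernel and the
posterior collapses it), so the default is matched to the noise scale
rather than to the span of observed effects.  The model-side Monte-Carlo
noise of a forward simulation (about 3–4 ms at these settings) adds in
quadrature and is kept below the tolerance.

**Sampler.**  One iteration of the Gibbs ABC sampler:

1. a fresh-simulation Metropolis–Hastings sweep proposing (LF_j, CW_j)
   jointly for every participant (participant steps are conditionally
   independent given the population draw and tbase, so the sweep is
   vectorized);
2. a second fresh-simulation sweep proposing CW_j only — cue weighting is
   the weakly identified direction and gets its own simulation budget;
3. two cheap LF-only sweeps: summaries are exactly proportional to LF, so
   the cached simulations rescale exactly to the proposal.  These moves
   hold the simulation randomness fixed, which is a valid move on the
   extended (parameters, simulation-noise) space that pseudo-marginal MH
   targets; the fresh-simulation sweeps refresh that randomness;
4. a tbase random-walk step whose weights are recomputed from cached
   simulations, and a *ridge move* that shifts tbase while translating
   every LF_j so each participant's mean simulated total RT is unchanged
   (given the cached noise the simulated mean RT is c_j·LF_j, so the
   compensation is a translation with unit Jacobian).  Without this move
   the tbase↔mu_LF ridge mixes an order of magnitude slower;
5. an exact conjugate normal-inverse-Wishart draw of the population mean
   and covariance given the current (LF_j, CW_j), converted to
   (mu_LF, mu_CW, sigma_LF, sigma_CW, rho).

Proposals outside `{LF > 0, CW >= 1}` are rejected outright (domain
truncation).  A 0/0 ratio of ABC weights is treated as 1 and counted, so
the chain cannot freeze when the tolerance is small; if *every*
participant's weight is zero after a sweep the run aborts with an error
suggesting a larger tolerance.  Proposal scales adapt per participant
toward 20–40% acceptance during burn-in only (factor
`exp(rate − 0.3)` per 100-iteration window) and are frozen afterwards, so
the retained chain is a valid Markov chain.  Default schedule: 4000
iterations, 1000 burn-in, no thinning.

Priors: NIW with location (0.2 s, 1.5), kappa0 = 1, nu0 = 4, scale
diag(0.01^2, 0.75^2) — weakly informative on latency factors of a few
hundred ms and cue weightings between 1 and about 4 (the upper range a
weighting prior should reach is about 4:1).

Initialization is data-informed: every CW_j starts at the prior location
and LF_j at the value whose noise-free mean RT (plus prior-mean tbase)
matches that participant's observed mean RT.

**Validation.**  The machinery is validated on a Gaussian pseudo-model
`x ~ N(theta, s^2)`, where the ABC target is available analytically: the
conjugate posterior with data variance broadened to `s^2 + delta^2`.  The
chain posterior mean and SD match within 5% at delta in {8, 4, 2}, and the
posterior SD shrinks monotonically toward the exact-likelihood SD as the
tolerance shrinks.  The population step is checked against closed-form NIW
results, and the full hierarchy against synthetic-truth recovery
(coverage of all five population CrIs; see the acceptance suite).

Interpretation caveats for the recovery setting (n = 60, mu_CW = 2,
sigma_CW = 0.5, 5 ms noise): the effect-to-CW gradient is shallow above
CW ≈ 2, so individual cue weightings are weakly identified and the
population correlation rho carries wide posterior uncertainty; its
credible interval is the honest summary, and single-dataset point
estimates of rho should be read with its posterior SD (≈ 0.2–0.3) in
mind.  This mirrors the situation with the published datasets, where
per-dataset correlation intervals frequently cross zero and only the
meta-analysis is decisive.

## Fisher-z random-effects meta-analysis

Each dataset fit contributes `z_k = mean(arctanh(rho draws))` and
`s_k = SD(arctanh(rho draws))` (floored at `1/sqrt(n_k − 3)` if the draws
are degenerate).  Passing moments rather than full draws keeps the stage
file-based and decoupled.  The pooling model is

    z_k ~ Normal(theta_k, s_k^2),  theta_k ~ Normal(mu_z, tau^2),
    mu_z ~ Normal(0, 1),           tau ~ half-Normal(0, 0.2),

sampled by Gibbs: theta_k and mu_z have exact normal conditionals; tau is
updated by a griddy-Gibbs step on a fixed 400-point grid on (0, 1] — the
grid keeps every other conditional exactly conjugate while the half-Normal
prior stays general.  The half-Normal(0, 0.2) scale is weakly informative
for a 13-study synthesis on the z scale; the grid upper bound of 1.0 is
far above any plausible between-study SD of Fisher-z correlations.  The
pooled correlation is `tanh(mu_z)` applied draw-wise; a split-chain R-hat
above 1.05 on mu_z or tau is recorded as a warning in the diagnostics and
the run manifest, never silently dropped.  Agreement and reflexive fits
enter as separate studies; subsetting by dependency is left to the caller.

## Pipeline and reproducibility

`run_study` is two-stage and file-based: per-block Gibbs ABC fits write
tidy chain CSVs, summary CSVs and Fisher-z inputs; the meta-analysis stage
consumes only the inputs CSV.  All randomness derives from one root seed
through a fixed drawing order, so a rerun with the same config and seed
reproduces every output byte-for-byte; the manifest records the config
snapshot, per-stage seeds, acceptance rates, diagnostics, and a SHA-256
checksum of every output file (timestamps and wall-clock timings are the
only run-dependent fields).  Recovery studies (`recovery_report`) simulate
replicate datasets from a stated truth, refit, and report per-parameter
bias and CrI coverage plus a posterior-predictive overlay of predicted vs
generating effects.

## Problem sizes

Default problem sizes were chosen so a full single-dataset fit (n = 60,
4000 iterations) runs in a few minutes on one core: 24 forward simulations
of 128 races per condition per weight evaluation, 100k races for
high-precision predictions, 250k-iteration chains for the toy validation.
All are configuration fields.

## Known limitations

* The ABC posterior is tolerance-broadened by construction; population SDs
  are mildly attenuated relative to a delta→0 posterior and the residual
  broadening from model-side simulation noise is not subtracted.
* Retrieval failures (threshold dynamics), inhibitory interference in
  grammatical sentences, fan effects, and base-level decay are out of
  scope; the simulator covers the two-chunk ungrammatical configurations
  only.
* Study-level inputs to the meta-analysis are posterior moments, which
  discards any non-normality of the per-dataset z posteriors.
* The population model is a truncated bivariate normal; bimodal or
  constant cue-weighting populations are not represented.
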