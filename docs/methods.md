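# Methods

## The task being modelled

The feedback-learning (FBL) paradigm presents, on every trial, one abstract
visual symbol together with one speech sound; the subject judges "match" or
"no match" and receives immediate correct/incorrect feedback.  A block
contains 48 trials over 6 sounds; each sound appears 8 times, half with its
correct symbol and half with a foil, in a pseudorandomized order that never
repeats a sound (hence never a pair) on consecutive trials.  Responses are
accepted within a 2,500 ms deadline; feedback stays on screen for a jittered
Normal(2.0 s, 0.5 s) duration followed by a Normal(2.5 s, 0.5 s) fixation.
Two blocks per task, two tasks (B uses visually modified symbols and new
sounds; at this level of abstraction both tasks share one design generator).

Design choices not fixed by the task description:

- **Foil assignment.** Which incorrect symbol accompanies a sound is left
  open by the paradigm description; the default gives each sound a single
  fixed foil symbol per block (the foil map is a derangement of the match
  map), so a block exposes 12 distinct pairs — the representation assumed by
  the learning model, where per-pair association trajectories form a small
  fixed set.  A random-foil-per-trial mode exists for design export, but the
  model modules refuse it (the association state would need a different
  bookkeeping).
- **Jitter truncation.** Normal jitters are redrawn below a 0.5 s floor
  (redrawing, not clipping, keeps the mean within ~1 ms of nominal).
- **Practice trials** are not generated: no learning model is applied to
  them and they contribute no analyzable data.

## The model

Learning follows a delta rule on the association strength (AS) of the
presented pair:

    AS_t = AS_{t-1} + eta * PE_t,    PE_t = f_t - AS_{t-1},  f in {1, 0}

with eta = eta_pos when PE > 0 and eta = eta_neg when PE < 0 (at PE = 0
either rate yields no change).  AS is the expected value of *answering
correctly about that pair*: correct feedback pushes it toward 1 whether the
pair is a true match (knowing it matches) or a foil (knowing it does not).
Consequently PE on correct trials decays to zero as pairs are learned.  The
single-rate variant ties eta_pos = eta_neg and is exactly nested in the
dual-rate variant.

The decision process is a two-boundary diffusion in accuracy coding: upper
boundary = correct response, relative start fixed at z = 0.5 (no response
bias at the start of learning).  The trial drift is

    v_t = v_mod * (AS_cor,t + AS_inc,t) / 2

where AS_cor and AS_inc are the sound's match-pair and foil-pair
associations — highest when both are known, intermediate when one is.
Choice and RT enter the likelihood jointly through the Wiener
first-passage-time (WFPT) density with boundary separation a and nondecision
time tau.  Inter-trial variability parameters of the full diffusion model
(sv, st, sz) are deliberately absent.

Two further conventions the sources leave open:

- The learning-rate subscripts are taken as eta_pos = rate for positive PE
  and eta_neg = rate for negative PE (one published figure caption labels
  both as "negative", an evident typo).
- The association state is keyed by (sound, symbol) *pair*, not by symbol
  alone; pair-keying is the only reading consistent with per-pair AS
  trajectories rising from 0 to 1.
- AS resets at each block boundary by default (each block is a fresh
  pseudorandomization of the same pairs); `reset_per_block=False` carries
  state across the two blocks of a task.

## WFPT numerics

The lower-boundary density factors into an exponential prefactor, kept in
log space, and a standardized series evaluated either by the small-time
image-charge expansion or the large-time Fourier sine expansion; per
evaluation the expansion needing fewer terms for an absolute tolerance of
1e-7 is chosen.  The upper-boundary density uses the reflection v -> -v,
w -> 1 - w.  Infeasible inputs (t <= tau, a <= 0) return -inf rather than
raising, so the sampler can treat them as zero-probability regions.  The
closed-form absorption probability p_upper = (1 - e^{-2vaw})/(1 - e^{-2va})
(gambler's ruin; w at v = 0) serves as an independent cross-check against
quadrature of the density.

## Synthetic cohorts

Subjects are drawn on the unconstrained scale from Normal(mu, sigma) per
parameter and pushed through the links (exp for a, tau, v_mod; inverse-logit
for the learning rates).  Trials are then generated by Euler-Maruyama
diffusion (unit diffusion coefficient, default dt = 1 ms, first-order
scheme whose O(sqrt(dt)) boundary-overshoot bias is verified to shrink with
dt in the tests); paths unabsorbed at 2.5 s are recorded as missing — no
feedback, no AS update, onsets keep the deadline as the trial's duration.

Default group parameters (synthetic study conditions, not fitted values):
natural-scale means a = 1.8, tau = 0.45 s, v_mod = 2.2, eta_pos = 0.5,
eta_neg = 0.2; unconstrained-scale sds 0.2, 0.15, 0.3, 0.5, 0.5.  They were
chosen once, by a three-candidate sweep of the thirds-binned summaries, to
produce the qualitative behavioral signature of the paradigm — guess-level
accuracy in the first third rising to roughly 0.85 in the last, weakly
decreasing RTs around 1 s, and a small missing rate (~4%).  What the
generator does **not** emulate: attentional lapses, response-button biases,
fatigue or drift in nondecision time, within-subject parameter variability,
and any stimulus-specific difficulty differences.  Passing recovery and
comparison tests therefore show the estimation machinery is correct under
the model's own assumptions, not that the model captures every feature of
human data.

## Hierarchical estimation

Non-centered parameterization: subject value = mu_p + sigma_p * z_sp on the
unconstrained scale.  Priors are weakly informative and overridable per
fit: Normal(0, 2) on group means, Half-Normal(1) on group sds.  An optional
tau link caps nondecision time below the subject's minimum RT via a scaled
inverse-logit.

The sampler is gradient-free: univariate slice sampling within a Gibbs scan,
augmented by three moves that target the model's known slow directions —

1. **Ancestral interweaving** of the group level: after each scan, (mu,
   sigma) are re-drawn conditionally on the subject *effects* (mu
   conjugately, log sigma by a cheap closed-form slice), which costs no
   likelihood evaluations and decorrelates group means from average subject
   offsets.
2. **Covariance-adapted direction moves** at the group level and per
   subject: slice updates along directions drawn from a running estimate of
   the posterior covariance, which travel the within-subject trade-off
   between drift scaling and learning rate that coordinate updates
   random-walk along.
3. **Kernel composition**: one reported iteration applies three full sweeps
   of the above (the way gradient samplers compose many integrator steps per
   iteration); `sweeps_per_iteration` is configurable.

Slice widths adapt during warmup only.  Chains are initialized near
data-informed values (nondecision time at half the minimum RT or 0.25 s,
whichever is smaller) with small jitter; feasibility (all responded RTs >
tau) is guaranteed at initialization and preserved by slice sampling.
Default run lengths are 4 chains x 10,000 iterations with 4,000 warm-up;
the analysis scripts and tests use desk-scale runs (hundreds to a thousand
iterations), which the composed kernel makes sufficient: the scaled
convergence benchmark (10 subjects, 4 chains x 1,000 iterations, 500
warm-up) reaches max split R-hat ~1.003 with minimum group-level effective
sample size around 600.

Convergence is declared at max split R-hat <= 1.01 (the split-chain
Gelman-Rubin statistic, floored at 1).  WAIC is reported on the deviance
scale, waic = -2 (lppd - p_waic), lower is better; lppd uses a stable
log-mean-exp and p_waic the per-trial variance of log likelihoods over
draws.  Missing trials contribute no likelihood terms and are excluded from
the WAIC matrix.  Fits are per task; a joint fit across tasks is possible by
relabelling but not the default, mirroring the per-task analysis design.

## GLM regressors and synthetic-BOLD validation

Stimulus onsets carry the trial's mean AS — the quantity that drives v_t —
as parametric modulator (the presented pair's AS is selectable); feedback
onsets (stimulus onset + RT) carry the PE.  Modulators are mean-centered
within condition.  Missed-trial stimulus and feedback onsets are pooled into
one nuisance regressor (the feedback onset of a missed trial uses the 2.5 s
deadline).  Event sticks on a 0.1 s micro-time grid are convolved with a
canonical double-gamma HRF — response gamma with mode exactly 6 s,
undershoot mode 16 s, ratio 1/6, 32 s support, unit-sum normalized — and
sampled at volume times (defaults 460 volumes, TR = 1.0 s, matching a
~7.7 min block).  FFT and direct convolution are both implemented and
asserted equivalent.  Motion or censoring regressors are accepted as
pass-through nuisance columns but never computed: no imaging data is in
scope, and the BOLD series used for validation are synthetic by
construction (design times known betas plus white noise), fit by OLS with
classical t-statistics.

## Problem sizes used

Test-suite and acceptance runs are sized for a single CPU: cohorts of 10-20
subjects x 96 trials; diffusion oracles at 1e5-1e6 paths; the dual-vs-single
WAIC comparison at 10 seeds x 20 subjects with short single-chain fits (WAIC
needs a posterior sample, not strict convergence diagnostics); parameter
recovery on one 20-subject cohort at 4 chains x 1,000/500; the group-mean
coverage property at 3 replicate 10-subject fits.  All thresholds (recovery
correlations, 9/10 WAIC preference, R-hat 1.01) are the full-scale criteria.

## Known limitations

- The Euler-Maruyama simulator is first-order; at dt = 1 ms its
  boundary-overshoot bias is visible as ~0.005 in absorption probabilities.
  An exact sampler is out of scope.
- Learning rates are weakly identified at 8 presentations per pair.  The
  positive-PE rate, which drives most updates in a learning regime, recovers
  at r ~ 0.6; the negative-PE rate sees only the ~25 error trials a subject
  makes and is effectively unidentified at the subject level — its posterior
  means shrink to the group mean and their correlation with truth is
  indistinguishable from noise.  Recovery assertions therefore cover a,
  tau, v_mod and the positive rate.
- The gradient-free sampler scales linearly in subjects and would need
  longer runs well beyond ~50 subjects; it is built for desk-scale cohorts.
- Real event logs are consumed only in the fixed-foil representation; logs
  from a random-foil protocol would require extending the association state.
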