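# Methods

## The task being emulated

`ratddm` analyses (and, lacking public raw data, synthesizes) behavior from a
rodent odor-guided two-choice task with blocked reward-value manipulations.
A session consists of four 60-trial blocks. Each trial starts with houselight
onset; the animal initiates by entering a central odor port within 5 s, holds
its nose-poke for 1 s through delivery of one of three odors (forced-left,
forced-right, or free-choice), and then responds at a fluid well within 3 s.
In blocks 1–2 one side pays after 0.5 s and the other after an adaptive long
delay; in blocks 3–4 both sides pay at 0.5 s but one side delivers two boli
instead of one. Side–value contingencies reverse between consecutive blocks,
so blocks 1 and 3 carry the "original" discrimination and blocks 2 and 4 its
"reversal". The adaptive long delay starts at 1 s, grows by 1 s every time
the animal picks the delayed side on a free-choice trial, and caps at 7 s;
forced-choice delays are yoked to it. Sessions alternate between a control
condition and an inhibition condition (optogenetic-style suppression of the
anterior cingulate cortex), with an LED flag raised on a random 50% of trials
in both.

Three latencies are recorded per trial: LO latency (houselight onset to odor
port entry — the task's attention proxy), RT (odor offset to odor port exit),
and MT (port exit to well entry), plus time spent in the well after reward.

## The generative model of a session

The simulator (`ratddm.task`) reproduces that structure trial by trial.

* **Odor schedule.** Each block draws a pseudorandom permutation with a fixed
  free-choice count (`free_choice_fraction`, default 1/3 — three odors — with
  the forced trials split evenly between sides). The fraction is not stated
  by the task description, so it is configurable.
* **Initiation and completion.** Initiation is Bernoulli(`p_initiate`); an
  initiated trial's LO latency is log-normal truncated to the 5 s window.
  Completion failures occur with probability
  `1 − p_complete_given_initiated`, and additionally whenever the diffusion
  decision time exceeds the 3 s response window (rare, < 1% at the default
  parameters).
* **Choices and RTs.** Completed free-choice trials draw (choice, RT) from a
  four-parameter drift–diffusion process whose upper boundary is the block's
  high-value side. The drift toward the high-value side ramps linearly over
  the first 20 trials of each block from a fraction of its asymptote (+0.2
  in original blocks, −0.5 in reversal blocks, the negative start expressing
  the carried-over association) so that the post-learning trials used by the
  model fit are exactly stationary. Forced-choice RTs are drawn from the same
  diffusion process; forced-choice *correctness* follows a logistic
  accuracy model, `P(correct) = σ(base + v·(value_gain + phase_gain·u))`,
  with `v = ±1` for high/low-value cues and `u` the within-block progress —
  enough to generate the qualitative value × phase accuracy pattern without
  claiming a mechanistic rule.
* **Reward and timing.** Free-choice trials always pay (at the chosen side's
  delay/size); forced errors pay nothing. Well times are gamma with a fixed
  bonus for double boli. Event time accumulates over latencies, delays, an
  inter-trial interval (log-normal), and occasional long off-task pauses
  (probability 0.045/trial, mean 170 s) that model disengagement. A session
  that exhausts its 2 h budget ends early: trials never presented produce no
  rows, so completed sessions are exactly those whose log holds all 240
  scheduled trials. Under the defaults this yields a majority of completed
  control sessions and a minority of completed inhibition sessions.
* **Condition effects** (`ratddm.presets.EffectSizes`) are applied
  session-wide — to both LED-on and LED-off trials — reflecting the
  assumption that suppression on half the trials acts tonically on task
  engagement rather than trial by trial.
  Defaults: initiation probability −0.07, completion probability −0.05,
  LO-latency location +0.25 (log s), off-task pause mean ×1.3, drift −0.8
  (delay blocks) and −0.3 (size blocks), starting bias +0.25 logits in size
  blocks. Forced-choice accuracy parameters are deliberately identical
  across conditions: the generator attributes condition differences in
  forced accuracy entirely to engagement and session completion, so any
  all-session accuracy gap emerges from those mechanisms rather than from a
  separate accuracy effect. An optional per-trial mode
  (`led_ddm_params_by_blocktype`) applies distinct DDM parameters on LED-on
  trials for sensitivity analyses.
* **Between-session variability.** `sample_session_config` draws each
  session's DDM parameters from Normal(group mean, group SD) on the
  unconstrained scale (SDs 0.15 / 0.10 / 0.25 / 0.30 for log α / log τ /
  logit β / δ), and draws a latent per-session attention factor that jointly
  shifts LO latency down and forced accuracy up, producing the negative
  latency–accuracy correlation the analysis stage measures.

What the generator does *not* emulate: video or photometry signals,
within-trial continuous dynamics beyond the named latencies, odor
counterbalancing across animals, rat identity (sessions are exchangeable
within condition), or any LED-by-trial behavioral effect under the default
settings. Passing tests therefore certify the analysis code and its
calibration on data *of this structure*, not conclusions about real animals.

## Behavioral measures

`ratddm.metrics` computes the session-level battery: % initiated (of
presented trials), mean LO latency, % completed (of initiated), rewards,
forced-choice accuracy (completed forced trials), free-choice high-value
preference (completed free trials), and mean RT / MT / well time. The
session, not the trial, is the unit for downstream statistics.

Free-choice learning cells use the first and last **10 completed free-choice
trials** per block (early/late), keyed by block type and discrimination. A
block must hold at least 20 completed free-choice trials so the windows are
disjoint; otherwise its cells are NA rather than silently dropped. Forced
accuracy cells use the first/last **20 scheduled trials** per block
(configurable) split by cued value; the early/late window width for forced
trials is not pinned down by the task description, and 20 keeps cells
populated at realistic forced-trial rates.

## Frequentist battery

Full-factorial ANOVAs use Type III sums of squares with sum-to-zero coding
(selectable), the convention that tolerates the unbalanced designs produced
by incomplete sessions. Post hoc two-sample t tests are pooled-variance
(df = n₁+n₂−2) with Bonferroni or Holm correction (`adjust_pvalues` corrects
a family jointly). Session completion uses Pearson's 2×2 chi-square without
continuity correction. The latency–accuracy association uses Pearson r per
condition and compares conditions with Fisher's r-to-z:
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`.

## DDM numerics

Parameters: boundary separation α > 0, nondecision time τ ≥ 0, starting bias
β ∈ (0,1) (fraction of α), drift δ; the diffusion coefficient is fixed at 1,
so α is in evidence units and δ in evidence units per second — all parameter
scales are relative to this convention.

The first-passage density uses the two classic series expansions of the
driftless kernel in boundary-normalized time — the small-time image series
and the large-time sine series — choosing per evaluation point whichever
needs fewer terms for a truncation error of 1e-7, then re-attaching the
drift factor `exp(−δαw − δ²(t−τ)/2)/α²`. The branches agree to ~1e-10 where
they meet; the implementation is numerically stable for t−τ ∈ [1e-4, 20] s
and α ∈ [0.3, 5]. A scalar JIT-compiled twin of the vectorized series serves
the sampler's inner loop and is asserted identical in the tests. The
closed-form hit probability is `P(upper) = expm1(−2δαβ)/expm1(−2δα)`, with
the exact value β returned at δ = 0.

Simulation uses Euler–Maruyama (default dt = 1 ms) plus a Brownian-bridge
within-step crossing test, which removes the leading O(√dt) discretization
bias of naive Euler first-passage sampling; the residual bias is O(dt). At
dt = 1 ms the L1 distance to the exact density is dominated by Monte-Carlo
noise up to ~10⁶ paths.

## Hierarchical model and sampler

Each completed session contributes one DDM parameter set per block type,
fit to its completed post-learning free-choice trials (block index > 20;
accuracy coding: upper boundary = high-value side; a stimulus-coded mode
exists). Sessions need ≥ 10 usable trials per block type; RTs outside
(0, 10 s] are dropped with a logged count. Session parameters are partially
pooled under group means and SDs per block type × condition on the
unconstrained scale (log α, log τ, logit β, δ). Priors: Normal(0, 20) on
group means and half-Normal(0, 20) on group SDs for boundary, bias and
drift; Normal(0, 1) / half-Normal(0, 1) for nondecision time. τ is
additionally capped at 0.95 × the unit's minimum RT to keep the likelihood
finite — standard DDM practice.

No gradient-based sampler backend is part of the package; instead the
posterior is sampled by an **adaptive Metropolis-within-Gibbs** scheme whose
structure exploits the model's conditional independencies, on the *centered*
parameterization:

1. session-level coordinates update by random-walk Metropolis,
   vectorized across all session × block-type units at once (given the group
   level their likelihoods are independent), with per-coordinate proposal
   scales adapted during warmup toward a 0.44 acceptance rate;
2. group means are conjugate normal given session parameters and group SDs
   and are drawn exactly (Gibbs);
3. group SDs update by univariate slice sampling with stepping-out.

The centered parameterization was chosen deliberately: with ~40 informative
trials per unit the session-level likelihood dominates its prior, which is
precisely the regime where centering mixes well and where a non-centered
parameterization couples the group mean to every unit. One stored iteration
comprises 8 full component sweeps (configurable, `sweeps_per_draw`), i.e.
thinning internal to the iteration; the reference iteration layout — 4
chains, 1,000 warmup, 3,000 sampling iterations — is kept at the stored
level. Chains start overdispersed around data-driven values (τ at 0.6 × the
unit's minimum RT, drift from the unit's accuracy, jittered per chain), and
a non-finite initial likelihood raises rather than sampling silently.

Convergence is monitored with the split-chain potential-scale-reduction
statistic computed for **every** group- and session-level parameter
(cross-checked against the reference implementation in `arviz`); a warning
fires at R-hat ≥ 1.02, the threshold the analysis treats as converged. Fits
are bit-for-bit reproducible under a fixed seed. Degenerate prior-only fits
(no data) are permitted and reproduce the prior, which the tests use as a
sampler check.

## Contrasts and recovery

For each parameter and block type, the contrast P is the fraction of paired
posterior draws (matched by chain and iteration — both conditions live in
one joint posterior) whose inhibition−control group-mean difference lies in
the hypothesized direction: boundary up, drift down, bias down. Because the
links (exp, logit) are monotone, P is identical on the constrained and
unconstrained scales. Verdicts: P > 0.95 significant in the hypothesized
direction, P < 0.05 significant opposite, otherwise none. Contrasts are on
group means; session-level draws are stored for the session-resolved
variant.

The recovery harness simulates a balanced study from known group parameters
(the "recovery design": free-choice fraction 0.55 and near-perfect
engagement, giving ≈ 80 post-learning free-choice trials per session with
the time budget off), runs the full prepare→fit→contrast pipeline, and
reports per-quantity bias, central-interval coverage, RMSE, contrast
verdicts and the maximum R-hat.

## Problem sizes and numerical choices

The validation suite uses desk-scale designs chosen as the smallest sizes at
which each property is sharply testable: density checks use 10⁶ Euler paths
per parameter set on a 12-point grid; the headline recovery uses 20 sessions
at the reference MCMC configuration; contrast calibration uses 10 replicates
of 10 null sessions with a shortened sampler (2 chains, 300 + 600, 6 sweeps)
whose posterior is checked only through its verdicts; type-I error checks
use 2,000 null replicates per test. The "large" drift reduction used for the
power check is −2.0 evidence units/s — larger than the entire control drift
— the scale at which a 12-session design has near-certain power; with ~40
trials per unit, drift and bias trade off strongly in accuracy coding (both
move choice fractions), so realistic effect sizes are *not* reliably
detectable at desk scale, and the harness makes no claim that they are.

## Known limitations

* Trial-level DDM parameters are constant within block type; no
  across-trial variability parameters (the model has exactly four
  components per unit), no contaminant-RT mixture.
* The 3 s response window truncates the slowest simulated decisions
  (≈ 1%), a mild model/generator mismatch absorbed by the posteriors.
* The sampler is random-walk based: posterior tails mix more slowly than a
  well-tuned Hamiltonian sampler's would; the R-hat gate and the
  reproducibility contract are the guard rails.
* The ANOVA treats cells from the same session as independent; with strong
  session random effects its type-I error for between-session factors is
  optimistic. The package keeps the conventional fixed-factor layout for this task
  family rather than introducing a mixed model.
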