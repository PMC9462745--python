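# Methods

## Task

An episode is a sequence of up to T_max/Δt = 200 scalar observations
s_k ~ N(μ, σ²/Δt), one per Δt = 10 ms step, with μ drawn once per episode
from N(0, σ_μ²).  The agent may answer "left" (μ < 0) or "right" (μ > 0) at
any step, ending the episode with reward 1 if the sign is correct and 0
otherwise; a "wait" on the last step ends the episode unrewarded (a *late
response*).  Step k covers time t = kΔt; the agent acts after observing
sample k.

σ is quoted in s^(−1/2) (white-noise convention): the per-sample standard
deviation is σ/√Δt = 1.8, so the information available about sign(μ) by
time t is independent of the discretisation.  This convention makes the
ideal fixed-t observer's accuracy ½ + arctan(σ_μ√t/σ)/π equal ≈ 0.85 at the
2 s deadline, consistent with the trained agent's ≈ 0.83; reading σ as the
per-sample deviation would make the task solvable within a few samples.

Difficulty maps to motion coherence via |μ| = 0.216·c/√(100 − c) (c in
percent).  The map follows from a model of dot displacement statistics in
which a fraction c of dots moves coherently: the mean of the pooled motion
signal scales as c and its standard deviation as √(1 − c).  The same map
makes the drift-diffusion CV law below come out as ((100 − c)/c²)^(1/4).
Under it, 50% coherence corresponds to μ ≈ 6.1 σ_μ (the value is sometimes
quoted as ≈ 5 σ_μ; the discrepancy is a property of the rounded constant
0.216 and is left as is).

At exactly zero coherence (μ = 0, a measure-zero event under training)
no correct side exists: such episodes are excluded from accuracy but enter
response-time and decision-aligned analyses, conditioning on the chosen
side where a "correct" side is needed.

## Integrator banks

Both banks share n_τ = 10 time constants log-spaced on [0.1 s, 10 s]
(ratio 100^(1/9) ≈ 1.668).  The discrete update is the exact zero-order-hold
solution x ← x·e^(−Δt/τ) + (1 − e^(−Δt/τ))·input, so the clock trace equals
1 − e^(−t/τ) to machine precision (forward Euler at Δt/τ = 0.1 would be
~0.5% off, and the closed form is used directly in the boundary analyses).
Banks reset to 0 at episode onset.

Intrinsic noise is *read-out* noise: actor and critic see
y = x + ξ, ξ ~ N(0, σ_I²) i.i.d. per τ, per bank, per step, with a single
draw shared by actor and critic within a step.  The noise does not
accumulate into the latent state.  This reading (over the alternative of
noise injected into the state) matches the description of the noise as
instantaneous-rate fluctuation, and it is the reading under which the
α_I rescaling for single-integrator comparisons (below) is exact.

## Actor, critic, and learning

The actor's six sums are Σ^s_a = Σ_τ θ^s_{a,τ} y^s_τ (the wait row uses
|y^s_τ|: a signal and its mirror image should equally justify waiting) and
Σ^c_a = Σ_τ θ^c_{a,τ} y^c_τ + b_a; action probabilities are
softmax(Σ_left, Σ_wait, Σ_right), computed with max-subtraction.  The
parameterisation is redundant under a common shift of the biases; no
canonical form is imposed.

The critic is linear in the same read-out.  Its signal feature is the
**signed** integrator value by default.  Because expected reward is
symmetric under a sign flip of the signal, the signed critic converges to an
almost time-only baseline V(t); this choice is load-bearing for learning
(see *Learning dynamics* below).  `critic_abs_signal=True` switches to
|y^s| features, making V track momentary evidence strength.

Updates are TD(λ) with eligibility traces, δ_t = r + γV(t+1) − V(t)
(V := 0 past the terminal step), e ← γλe + ∇, parameter += lr·δ·e.
Within an episode the parameters are held fixed and the per-step updates
accumulate; they are applied at episode end.  With λ_actor = 1 the actor
update is then exactly REINFORCE with the critic as a baseline (unbiased);
the default λ = 0.6 trades a little bootstrap bias for much lower variance.

Defaults (package choices, exposed in `TrainingConfig`):

| parameter | default | rationale |
|---|---|---|
| lr_actor | 8e-3 | fastest stable actor rate; accuracy floor reached well within ~1e5 episodes |
| lr_critic | 2e-3 | slower critic tracks the value surface without chasing episode noise |
| λ (actor, critic) | 0.6 | variance/bias balance; λ ≥ 0.9 is markedly noisier, λ = 1 unbiased but slow |
| γ | 1.0 | episodic, terminal-only reward, ≤ 2 s episodes |
| b_wait init | 8.0 | initial policy almost always waits out the deadline (see below) |
| θ, critic init | 0 | symmetric start |
| n_episodes_max | 150,000 | performance has essentially plateaued; signatures peak earlier |
| checkpoint_every | 2,000 | halting-rule resolution |
| eval episodes / checkpoint | 2,000 (+2,000 per coherence) | frozen held-out seeds, so checkpoints are comparable |

### Learning dynamics and the impatient local optimum

The reward landscape of this task has (at least) two basins.  In one, the
agent decides quickly (~0.15 s) on fluctuations of the fastest integrators;
accuracy saturates near the ideal value *for that response time* (~0.65).
In the other, the agent waits ~1 s, leans on slow integrators and reaches
~0.83.  Two design choices reliably select the good basin:

1. **High initial waiting bias.**  With b_wait = 8 the untrained policy
   waits out most episodes, so early experience exercises the slow
   integrators and the timeout penalty is felt.  Initialisations that act
   early (b_wait ≤ 5) reproducibly converge to the impatient basin and stay
   there: once decisions are driven by short-lived bursts, globally
   suppressing action (raising b_wait) no longer raises reward, so the
   gradient cannot escape.
2. **The signed-feature critic.**  An |y|-feature critic tracks momentary
   evidence, and training with it lands in the impatient basin under every
   learning-rate setting tried; the signed critic's nearly time-only
   baseline V(t) removes the time-correlated component of the return from
   the actor's credit and reliably yields patient, accurate policies.

### Halting

Each checkpoint records held-out accuracy, signal neutrality and the scalar
property (frozen evaluation seeds).  Training runs to n_episodes_max; the
returned parameters are the checkpoint with **maximal signal neutrality
among checkpoints whose accuracy is ≥ 0.81** (falling back to the most
accurate checkpoint if the floor is never met).  Under the defaults the
floor is typically crossed between 40k and 60k episodes and the
neutrality peak sits between 60k and 110k; with ten times longer training
accuracy gains only about one more percentage point while signal
neutrality collapses to a fraction of its peak — the signature marks a
"good-enough" strategy, not the asymptotic one.

### Accuracy definition

Accuracy is the **fraction of correct choices among decided episodes**
(μ = 0 excluded); late responses are tracked separately as the
late-response fraction.  Under this definition the 0.81 floor, the halting
range and the model-comparison margins are jointly consistent in our runs;
counting late responses as errors is available as
`accuracy(decided_only=False)` (equal to mean reward) and is the measure
used when comparing against the thresholded-integrator models, whose
threshold is itself optimised under it — under the decided-only measure a
high-threshold integrator could "win" by answering only the easy episodes.

## Comparison models

* **Thresholded single integrator** (Ornstein–Uhlenbeck decision process):
  one signal integrator; 'right' at the first step its noisy read-out
  reaches +Θ, 'left' at −Θ.  Θ is grid-searched (51 points on [0, 1]) with
  common random numbers across candidates, maximising reward-based
  accuracy; ties break toward smaller Θ.
* **Single-timescale agent**: the same architecture with one τ for both
  banks — 9 parameters — trained identically.
* **Clockless agent**: full signal bank, clock weights frozen at zero.

When a single-integrator model is compared with the agent, its read-out
noise is rescaled by α_I = max_τ|θ*_τ| / √(Σ_τ θ*²_τ) ∈ [1/√n_τ, 1]
(θ* = trained 'right' signal weights), equalising the effective noise of the
agent's weighted average of independently-noisy integrators; α_I ≈ 0.45
for trained agents.  The square-root form is adopted because it alone
satisfies both limiting cases (α_I = 1 for one active integrator, 1/√n_τ
for equal weights, the noise reduction of an n-fold average).

The drift-diffusion CV law ((100 − c)/c²)^(1/4) is exact (prefactor 1) for
the no-leak integrator at threshold Θ = σ²/0.216 = 0.15; its coherence
dependence is threshold-free.  The first-passage oracle in the tests
simulates at that threshold with dt = 0.1 ms, keeping discretisation bias
well under Monte-Carlo error.

## Signature measures

* **Signal neutrality**: mean ΔΣ_right aligned to decision time over
  correct 'right' episodes ('right'-choice episodes at 0% coherence), for
  the six coherences {0, 3.2, 6.4, 12.8, 25.6, 51.2}%, on lags up to 600 ms
  before the decision; a coherence's curve is truncated where fewer than
  100 episodes reach that lag, and dropped entirely if no lag qualifies.
  All curves are jointly min-max rescaled to [0, 1]; the measure is the
  inverse of the mean (over lags with ≥ 2 defined curves) maximal pairwise
  distance.  Invariant under common affine transforms by construction.
* **Scalar property**: inverse of the range of response-time CVs across the
  six coherences (decided episodes; unbiased standard deviation).
* Both inverse measures are capped at 1e6 when the underlying distance or
  range falls below 1e-9, so perfect collapse stays finite and plottable.
* **Boundary strip**: the central 80% interval (10th–90th percentile) of
  ΔΣ^s at the decision step among correct 'right' decisions, per time bin
  (default bin = Δt; bins with < 20 decisions flagged, not interpolated),
  paired with the deterministic moving threshold
  ΔΣ^c(t) = Σ_τ(θ^c_wait − θ^c_right)(1 − e^(−t/τ)) + b_wait − b_right.
  ΔΣ^c uses the 'right' clock sum; trained left/right clock weights are
  nearly equal, and the 'left' variant is available through the same
  function.
* **Gamma fits** of response-time histograms use maximum likelihood with
  location fixed at 0; shape-invariance across coherences is displayed by
  rescaling fitted densities to unit mean.

## What the synthetic task does and does not emulate

The generator *is* the study system: a stationary Gaussian signal with
episode-level difficulty drawn from a fixed distribution and a hard
response deadline.  It does not emulate visual motion energy, spatial
receptive fields, non-decision (motor) latencies, sequential effects
between trials, or slow non-stationarities of real experiments.  Passing
tests therefore demonstrate properties of the learning architecture on the
idealised task, not quantitative fits to animal behaviour; the psychometric
comparison against the experimental reference curve is qualitative (an RMS
deviation is reported, with no pass threshold).

## Problem sizes

Defaults above are the study conditions.  The test suite compares models
over five training seeds: seed 0 at the default checkpoint cadence, seeds
1–4 with 15k-episode checkpoints and 500-episode coherence batches (same
learning trajectory, cheaper diagnostics); signal-neutrality and CV-range
comparisons use 1,500 episodes per coherence, accuracy comparisons 10,000
common episodes per seed; the extended-training check runs a single
1e6-episode course.  The acceptance script trains one default agent and
evaluates 10,000 fresh episodes.

## Known limitations

* Reward-based accuracy of the halting agent is ≈ 0.79–0.81 (late-response
  fraction 2–5%), and its margin over the best thresholded integrator on
  that measure is small (≈ 0.5–1.5 points, averaged over seeds); the
  decided-only margin over the *trained* ablations is comfortable.  The
  architecture cannot express a sharp "always answer just before the
  deadline" rule (the clock code is smooth in t), which bounds how small
  the late-response fraction can get at long mean response times.
* Single-run signatures fluctuate: signal neutrality at the peak varies
  roughly twofold across seeds; ordering tests therefore average over the
  five matched seeds.
* Absolute response-time scales beyond the 2 s deadline (multi-second mean
  response times at low coherence) are outside this configuration's reach
  by construction; the scalar property is assessed through the CV range,
  not through those absolute means.
* Training hyperparameters are package choices (see table); no claim is
  made that they match the original study's unpublished values, only that
  they reach the same operating point under the same architecture.
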