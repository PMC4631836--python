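# Methods

## The model

`aimdp` simulates an agent solving a finite-horizon, partially observed
Markov decision process by active inference. The agent's generative model is
specified by

* an observation model **A** — column-stochastic, column *j* giving
  P(outcome | hidden state *j*);
* controlled transition models **B**(*u*) — one column-stochastic matrix per
  control state, entry (i, j) giving P(next = i | current = j, control = u);
* a terminal preference **C** — a log-probability vector over hidden states;
  exp(**C**) is the distribution over final states the agent believes,
  a priori, that it will reach, so ln-preference plays the role of utility;
* a Gamma(prec_shape, prec_rate) prior over the *precision* γ of beliefs
  about control states.

Policies are admissible control sequences over the trial's T−1 transitions.
A policy's value from state *s* at epoch *t* is the negative KL divergence
between the predictive distribution over final states under that policy and
the preferred distribution exp(**C**) (KL control):

    Q(s, k) = −KL[ P(s_T | s_t = s, policy k) ‖ exp(C) ] ≤ 0.

Predictive distributions use the probability-domain posterior means E[B(u)],
while the evidence terms of the state update use the expected-log matrices —
following the two distinct parameter expectations that a Dirichlet posterior
supplies.

### Within-trial inference

Each epoch runs an interleaved fixed-point iteration (16 rounds by default)
of three updates, in order:

1. **State estimation.**
   ŝ_t = σ( Â·o_t + B̂(a_{t−1}) ŝ_{t−1} + γ̂ · Q π̂ ), where Â·o_t is the
   expected-log likelihood row selected by the observed outcome, B̂ is the
   expected-log transition matrix, and σ is the normalized exponential. The
   third term is an *optimism bias*: perception is pulled toward valuable
   states in proportion to precision. At the first epoch the prediction term
   is replaced by the log of the known initial-state distribution.
2. **Policy evaluation.** π̂ = σ( γ̂ · Qᵀ ŝ_t ): a softmax over policies with
   precision as inverse temperature.
3. **Precision.** γ̂ = prec_shape / (prec_rate − π̂·Qᵀŝ_t). Since Q ≤ 0,
   inferred precision is bounded above by the prior mean
   prec_shape/prec_rate; it rises when observations raise the expected value
   of the policies. This bound is what makes an external clamp above the
   prior mean "impossible" for the agent to explain without revising its
   state beliefs.

Actions are sampled at each transition from the policy posterior marginalized
onto the control prescribed at that transition.

### Learning

The A and B parameters carry column-wise Dirichlet beliefs (conjugate to the
multinomial likelihood). After each trial the concentration parameters
accumulate the soft evidence from the trial's final per-epoch state
posteriors:

* a_post[o_t, j] += ŝ_t[j] for every epoch;
* b_post(a_{t−1}) += ŝ_t ⊗ ŝ_{t−1} for every transition, only in the matrix
  selected by the action actually taken.

One unit of mass is added per epoch and per transition, so the implicit
learning rate is 1/(total concentration): beliefs based on more evidence
move less. Updates are applied once at trial end (online, per trial) using
the final, most informed posteriors — accumulating every within-trial
iteration would double-count revisions of the same beliefs. Precision never
appears in these updates; the accumulation functions do not even accept it
as an argument. This separation (a Markov blanket between precision and
parameters) is why clamping precision can change *which* states are inferred
— and hence what is learned — without touching the learning rule itself.

### Free energy

Per-epoch variational free energy is reported in the minimized convention,
complexity minus accuracy:

    F_t = −ŝ_t·Â·o_t + KL[ŝ_t ‖ E[B(a)]ŝ_{t−1}] + KL[π̂ ‖ σ(γ̂ Qᵀ ŝ_t)]
          + KL[Γ(α, α/γ̂) ‖ Γ(α, β)] + KL[Dir(post) ‖ Dir(prior)]

The policy complexity is measured against the value-based policy prior
σ(γ̂Qᵀŝ) implied by the generative model (it is ≈0 at the fixed point); a
uniform-prior convention would add ~ln 2 per epoch as the agent becomes
confident and would mask the free-energy reduction that accompanies
learning. With online accumulation the Dirichlet term is identically zero
within a trial (each trial's effective prior is the running posterior), so
session runners skip computing it; the standalone function retains the
closed form and is verified against a Monte-Carlo oracle. A trial's
accumulated free energy (the "Action") is the sum of its per-epoch values.

## The conditioning task

Fourteen hidden states (two pre-cue, two cue, a pair of delay states for
each of the four cue×response combinations, win, no-win), five observations
(null, two cues, two outcomes), three controls (do nothing, response 1,
response 2), six epochs. The agent always starts in pre-cue 1, moves
deterministically to pre-cue 2, sees one of two cues with equal probability,
responds at the third transition, waits two delay epochs, and transitions
stochastically to win/no-win with the (cue, response) pair's true reward
probability. Default contingencies: each cue rewards one response at 0.8 and
the other at 0.2, mirrored across cues. A single-cue variant
(response 1 → 0, response 2 → 0.5) serves the stimulation-learning
experiment.

The policy set contains the two respond-then-wait sequences; a
do-nothing-throughout policy is excluded by default because the task defines
delay states only for cue×response pairs (a flag can add it). Because each
delay pair is unique to a cue×response combination, the hidden state encodes
the agent's history and temporal credit assignment is solved by filtering
alone.

### Agent priors

* Known transitions: concentration 512 (`conc_strong`) on the true entry,
  1e-6 (`conc_floor`) elsewhere — strong enough to be effectively fixed over
  a session, while the floor keeps the digamma finite.
* Unknown delay→outcome columns: 1.0 on no-win, 0.4 on win, floor elsewhere —
  a weak prior that reward is unlikely (mean win probability 0.286).
* Observation model: 512 on the true outcome per state and 1/16
  (`a_conc_floor`) elsewhere. The floor for A is deliberately much larger
  than for B: the *expected-log* likelihood scales like ψ(floor) ≈ −1/floor,
  so the floor fixes how many nats of contrary evidence a precision clamp
  must explain away. At 1/16 the expected observation accuracy is still
  ≈ 0.9995 per state, and the stimulation-induced inference flip occurs
  within the 8–16 clamp range; a floor of 1e-6 would make observation
  evidence ~1e6 nats and no finite clamp could ever overturn it.
* Preference: exp(C) puts 0.95 on the win state, essentially all of the
  remaining 0.05 on no-win (≈3 nats of utility difference), a floor of 1e-6
  elsewhere.
* Precision prior: Gamma(8, 1) — prior mean precision 8, so the depletion
  clamp (0.1) is far below and the stimulation clamp (16) far above anything
  the agent can infer on its own. The hyperparameters are not learned.
* 16 variational iterations per epoch, matching the deconvolution kernel's
  time constant so one epoch spans one kernel time constant.

## Interventions

A clamp schedule fixes γ̂ at chosen epochs of chosen trials (optionally only
after a particular action). During clamped epochs the precision update is
skipped entirely — the trace shows a flat plateau — and every clamped
iteration still feeds the clamped γ̂ through the ordinary state and policy
updates. Depletion clamps all six epochs at 0.1; stimulation clamps only the
final epoch at 16 (clamped for all 16 iterations of that epoch, consistent
with a sustained stimulation pulse).

## Dopamine readout

The simulated dopamine signal is the sequence of innovations d obtained by
deconvolving the per-iteration precision trace with the exponential kernel
K(τ) = exp(−τ/16) (iterations as time bins; the kernel time constant is
stated in iterations). The convolution system is lower-triangular and solved
exactly; convolving the result reconstructs the trace to machine precision.
The first epoch's samples carry a boundary artifact (the deconvolution
assumes zero signal before the trace begins) and are discarded in all
experiment outputs.

A scalar per-epoch *phasic response* is the innovation summed over the
epoch's block minus the innovation a constant precision (at its value on
entering the epoch) would have required; it is ~0 for flat epochs and
proportional to the within-epoch precision change for step-like traces.

Spike histograms map innovations to Poisson rates with four spikes/bin per
unit innovation over a four spikes/bin background. By default negative
innovations are rectified (rate = background + 4·max(d, 0)); a `baseline`
mode (rate = max(background + 4·d, 0)) lets omission dips appear as
below-background firing, since the population-level signal plainly carries
signed dips. Histograms average 64 simulated trials.

## Experiments and problem sizes

All experiments are pure functions of their arguments and a seed; sessions
use independent child streams spawned from the seed. Defaults follow the
study design (256 sessions); the test suite and the acceptance script run 64
sessions per arm, which keeps every averaged quantity well inside its
tolerance while completing in a few minutes on one CPU.

* **Learning**: 128-trial sessions on the default contingencies; outputs
  per-trial session-mean expected win probabilities per contingency and mean
  free energy. At 64 sessions the trial-128 estimates land within ±0.04 of
  truth and free energy falls ~17 → ~4.5.
* **Depletion**: γ clamped at 0.1 for trials 1–32, free for trials 33–48,
  against a never-clamped control arm. Choice accuracy is chance-like under
  the clamp while the estimate trajectories track the control arm (mean
  absolute difference ~0.03; the arms' *high*-contingency estimates differ
  transiently because the greedy control visits them about twice as often).
* **Stimulation/inference**: deterministic replays of a naive agent seeing
  cue 1, taking response 1, observing no-win; final-epoch clamps swept
  8 → 16 in 0.1 steps. Unclamped, the no-win posterior exceeds 0.999; the
  win posterior rises monotonically with clamp strength and dominates well
  before 16.
* **Stimulation/learning**: the single-cue task with an action-contingent
  final-epoch clamp of 16 following the never-rewarded response, 48-trial
  sessions. The clamp makes the agent infer wins it never saw, those false
  wins accumulate into the transition beliefs, and preference reverses.
* **Dopamine dynamics**: four fixed trial types (high/low-expectancy cue ×
  win/no-win) replayed through naive and learned beliefs, plus a replay of
  the high-cue/response-1/win trial after every one of the first 64 trials
  of each session (transfer curves). The four conditions all replay
  response 1 so that they differ only in expectancy: under the symmetric
  default contingencies each cue's *own* best response has equal value, so
  conditioning on the best response would erase the high/low contrast. With
  this construction the learned low-expectancy deflection appears at the
  first post-choice epoch (when the agent, having seen which delay chain it
  entered, revises its prospects) rather than at the cue itself.

## Numerical choices and degenerate inputs

* Simplex checks at 1e-10; softmax is max-subtracted.
* KL divergence floors its second argument at 1e-16 (deterministic
  transitions produce exact zeros); the first argument's zeros contribute 0.
* Nonpositive Dirichlet concentrations, non-finite softmax inputs, invalid
  state/outcome/control indices, and nonpositive clamp values raise
  ValueError.
* Ties in the "objectively correct response" break toward the lower response
  index; with sampling-based action selection no other tie-breaking is
  needed.
* 1-based trial/epoch/state labels in exported tables, 0-based indices in
  code.

## What the generator does and does not emulate

The environment generator reproduces the task's generative process exactly:
equiprobable cues, deterministic pre-cue and delay chains, Bernoulli
outcomes at the stated contingencies. It does not model reaction times,
motor noise, trial-to-trial drift in contingencies (no volatility or
forgetting), Pavlovian variants, vigor/effort, or aversive outcomes; passing
tests therefore demonstrate the model's behavior under stationary,
fully-specified contingencies, not robustness to real-data nuisances such as
nonstationarity or observation noise in the cue channel.

## Known limitations

* Precision hyperparameters are fixed, not learned.
* Online filtering only: no backward smoothing over past states, so evidence
  arriving late in a trial does not revise earlier epochs' stored posteriors
  (learning uses each epoch's final posterior as-is).
* Policies are fixed control sequences; they do not branch on future
  observations.
* The free-energy trace is comparable within a configuration but its
  absolute level depends on convention choices (policy prior, skipped
  parameter term) documented above.
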