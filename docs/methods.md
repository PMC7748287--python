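# Methods

This note documents the model implemented by `spikeplan`: its assumptions,
the parameters that matter, the numerical design decisions taken where the
design was genuinely open, what the simulated task does and does not show,
and known limitations.

## Model

### Architecture and dynamics

The planning network is a neurally instantiated hidden Markov model. The
400-unit associative layer carries the hidden state: at each discrete time
step exactly one unit spikes, sampled from a categorical distribution over
units, so the layer's activity is a sample path of a latent-state chain.
The 10-unit input and output layers are the observation model (input:
evidence from the world; output: generative reconstruction of the
predicted event), split into two one-directional layers because real
synapses are one-directional. A 2-unit goal layer conditions the hidden
state distribution on the pursued goal.

Each free-running layer is a winner-take-all circuit. The sampling
potential of unit *k* is

    u_k(t) = ( û_k(t) + ν·ξ − g_r·r(t) ) / τ,

where û_k sums the synaptic drive (input + goal + recurrent), ν is the
membrane noise standard deviation, r(t) = r0·exp(−age/τ_r) is a refractory
subtraction indexed from the unit's own last spike (zero if it never
fired), and τ is the softmax temperature of the lateral-inhibition
competition. One spike per layer per step is drawn from softmax(u).

Two deliberate choices here:

* **The temperature applies to the associative and output competitions,
  not only to the exploration network.** The STDP rule's potentiation
  fixed point is −ln(c) ≈ 0.40 at the fitted c, so with a unit-temperature
  softmax over 400 units the maximum attainable selectivity is
  e^{0.4}/400 ≈ 0.004 and the normalized entropy cannot leave ~0.95: the
  arbitration threshold ε = 0.74 would never be crossed and planning would
  never engage. At τ = 0.02 a single trained connection is worth 20 nats,
  entropy collapses after one experience of a stimulus, and the whole
  behavioural arc (entropy-gated planning, inverted-U reaction times,
  exploitation) emerges. This placement also makes the searched noise
  range ν ∈ [0.01, 0.1] functionally meaningful (ν/τ ≈ 1 nat of choice
  stochasticity at the competition scale).
* **The recurrent drive pools a short decaying trace of recent spikes**
  (x_a(t) = max of the decayed trace and the current spike, decay
  constant `epsp_tau` = 1.25 steps) rather than only the previous spike —
  EPSPs outlasting a single time bin. This is load-bearing: with strictly
  one-step drive, "re-use a hidden-state group in its own context" and
  "wrongly re-use a foreign group under a matching input" produce exactly
  the same drive, so context-specific (stimulus × action) hidden causes
  can never form. Group-level trace sums separate the two cases
  statistically: links inside a group are re-potentiated on every use
  (roughly half are live at any moment under order rotation), while links
  from a foreign context are uniformly depressed.
* **The output layer carries no refractory** (`r0 = 0` there). The
  refractory's function — forcing distinct units to fire in sequence so
  events unroll into chains — is an associative-layer function; the output
  layer is a reconstruction readout whose spike counts must be free to
  repeat an event for its whole duration, otherwise the "fired the most"
  readout degenerates into ties. The readout's synaptic drive pools the
  positive (excitatory) output weights of the recently active hidden
  units, inhibition being already supplied by the competition.

### Learning

World-model weights (input→associative, associative recurrent,
associative→output) are updated only during the learning replay of each
experienced trial: the input layer is driven by the colour, the executed
action and the observed feedback for five steps each; the output layer is
clamped to the same events one step later (teacher forcing, matching the
one-step associative→output lag); the associative layer free-runs. The
STDP rule

    Δw_post,pre = ζ · s_post · (e^{−w} · s_pre − c)

is applied with the *recent window* as the presynaptic signal for the
recurrent and output matrices (a unit counts as pre if it fired within
`stdp_window` = 5 steps, one event duration), and the current input
pattern for the input matrix. Weights are bounded to
[floor, −ln(c)]: the cap is the rule's own potentiation fixed point (the
raw rule is numerically unstable — depression is unbounded below and
potentiation is ζ·e^{−w}, so a single co-firing of a long-depressed pair
explodes), and the floor is per matrix:

* input and output floors at −0.9: depression is a hard context
  exclusion, far below the cap, so a unit recruited by one event is
  effectively unavailable to others;
* recurrent floor at −0.4: a soft temporal-order preference. Its value
  sits in a window fixed by the architecture's own constants: the
  depressed background must stay above cap − r0 = −0.7 (else a
  refractory-suppressed trained unit still beats the background and one
  unit monopolises whole phases), and low enough that a foreign group's
  trace-summed depression (≈ Σx·floor/τ) outweighs its 20-nat input
  advantage;
* recurrent weights are initialised just *below* their floor
  (`rec_init` = −0.5): a transition once observed and later depressed
  still outranks one never observed, which is what holds groups together
  through link churn (a zero initialisation collapses even
  single-contingency learning).

Goal→associative weights follow the bounded reinforcement rule with
pseudo-reward m = −1 applied during planning after a cycle whose readout
*definitely* mispredicted the goal (a cycle that read out no event
identified nothing to punish), and m = +1 after real goal achievement.
Two refinements matter:

* the m = −1 eligibility trace covers only units that fired *after* the
  input clamp — the freely sampled "choice". Punishing the stimulus-driven
  prefix is never self-limiting (it fires in every cycle regardless of the
  choice) and demonstrably destroys the stimulus representation; punishing
  the choice is self-limiting (a suppressed branch stops firing and stops
  being punished);
* the goal term enters the drive with gain `goal_gain` = 0.15: a
  saturated goal bias (±w_max/τ = ±25 nats at full gain) would override
  the learned structure itself, letting goal-positive attractors capture
  other stimuli's trajectories; at gain 0.15 the saturated bias (≈ ±3.8
  nats) decides between otherwise-tied branches and nothing else.

The exploration network (6 colour × goal inputs → 5 actions) selects by
softmax at temperature τ and learns by punishment only
(inhibition-of-return); successful actions are never reinforced there.

### Arbitration

The world model's per-cycle uncertainty is the mean over the 15 steps of
the associative sampling distribution's Shannon entropy, normalized by
ln(400). The threshold starts each trial at ε and falls by δ per failed
cycle; H at or above threshold hands control to exploration, H below
threshold either executes a goal-matching plan or punishes and replans.
Equality counts as "too uncertain" (the measure-zero boundary case).

## Parameters

| name | default | meaning |
| --- | --- | --- |
| ζ `zeta` | 0.96 | STDP learning rate |
| c | 0.67 | STDP depression constant; potentiation fixed point −ln(c) |
| η `eta` | 0.008 | goal / exploration learning rate |
| τ `temperature` | 0.02 | softmax temperature of the competitions |
| ν `noise_sd` | 0.02 | membrane noise SD (on û, before tempering) |
| ε `epsilon` | 0.74 | entropy threshold at trial start |
| δ `delta` | 0.12 | threshold decrement per failed cycle |
| r0, τ_r | 1.1, 9.5 | refractory amplitude and decay (steps) |
| w_max | 0.5 | goal / exploration weight bound |
| K, T | 400, 15 | associative units; steps per trial/cycle |

The first seven are the searchable parameters (ranges in
`spikeplan.SEARCH_RANGES`); defaults are the fitted values. The remaining
implementation constants (`stdp_floor_*`, `stdp_window`, `epsp_tau`,
`rec_init`, `goal_gain`, `readout_tau`, `init_sd`) were calibrated once on
an isolated world-model coherence microbenchmark — train fixed
contingencies through the learning replay, then measure the fraction of
planning cycles whose (action, outcome) readout is a truly experienced
pair — and on the considerations above; they are exposed on `ModelParams`
but are not part of the searched space.

## What the simulations do and do not show

The task environment is itself the data-generating process: stimuli,
staircase designations and feedback are produced exactly as the protocol
prescribes (pseudo-random colour triplets; the 2nd/4th/5th response to the
dynamically designated S1/S2/S3 declared permanently correct; a second,
goal-switched phase with persistent contingencies). Simulated behaviour
therefore shows what the *architecture* does under the protocol — learning
curves, reaction-time profiles in planning cycles, flexibility — not what
humans do. Human reference curves are not bundled (none are tabulated);
the fitting harness accepts any user-supplied curve table, and the
included synthetic reference (ideal agent with lapses, inverted-U
reaction-time template) exists only to exercise the harness. Reaction
times are in planning cycles, not seconds; no habit system exists, so
asymptotic human automatisation is out of scope.

## Numerical notes

* Softmax uses max-subtraction; entropy uses the 0·ln 0 = 0 convention.
* Categorical sampling is the only tie-breaker in the core; the readout
  breaks count ties uniformly at random.
* Every simulation is reproducible from (parameters, seed); the parameter
  search derives per-combination generators from (master seed, index) so
  it can be partitioned across processes without changing results.
* A trial always runs at least one planning cycle (reaction time ≥ 1);
  termination is guaranteed by f = ⌈ε/δ⌉ at the latest, with a
  `max_cycles` = 50 safety cap.
* The goal unit stays clamped during both planning and the learning
  replay (configurable); membrane noise likewise applies in both phases
  (configurable), since the original description leaves both open.

## Known limitations

* **Slow representational drift.** Hidden-state groups only ever gain
  members: when a phase's group is momentarily exhausted (all members
  refractory) a fresh unit is recruited and keeps its input weight cap
  forever. Over many trials this dilutes link reliability, and shared
  structure — above all the two feedback events, which serve every
  (colour, action) context — suffers link churn in which a capped
  connection dies after a single missed co-firing. The consequence is a
  late-session exploitation plateau around 60–75 % correct rather than
  ~90 %: occasional false-positive plans (a wrong action whose simulated
  feedback reads "correct" through a stale branch) persist because an
  executed failure trains only the exploration component, never the goal
  weights. S1, designated earliest and therefore exposed longest, shows
  this most clearly: its learning curve starts at the staircase-forced
  0.5 and plateaus near 0.55 instead of rising a further 0.3.
* One-step planning only: a trial is one colour-action-feedback episode;
  multi-step readout is not implemented.
* The arbitration component is algorithmic, not neural.
* Discrete time with one spike per layer per step; no continuous-time
  Poisson variant.
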