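# spikeplan

A generative spiking neural-network model of goal-directed behaviour and
one-step planning, together with the visuomotor staircase task used to
study it.

## The problem

Goal-directed agents plan by internally simulating what the world will do:
*planning as inference* conditions a generative world model on a desired
outcome and samples action sequences likely to produce it. Grounding this
on spiking neurons raises two problems this package's architecture
addresses: the world model must be **learned while it is being used** (the
task is new — there is no offline pre-training), and it must be learned
**unsupervised**, from observed events alone. The architecture solves the
first with an arbitration mechanism that plans when the world model's
entropy is low and explores when it is high, and the second with a
spike-timing-dependent plasticity (STDP) rule that lets a recurrent
winner-take-all network learn hidden causes of observations and their
temporal structure, i.e. a neurally instantiated hidden Markov model.

## The model

Four spiking layers form the planning network: a 10-unit input layer (3
colour stimuli, 5 button-press actions, 2 feedback outcomes), a 2-unit
goal layer, a 400-unit recurrent associative layer (all-to-all, no
self-connections) and a 10-unit output layer mirroring the input layer.
Each layer is a discrete-time winner-take-all circuit: unit *k*'s
potential is

    u_k(t) = Σ_i w_ki s_i(t−1) + Σ_g w_kg s_g(t−1) + Σ_a w_ka x_a(t−1) − r(t) + ν ξ

(input, goal and recurrent drive, an exponentially decaying refractory
term r = r0·exp(−t/τ_r) indexed from the unit's own last spike, and
Gaussian noise), and one spike per step is sampled from
softmax(u/τ) — lateral inhibition abstracted as a softmax competition at
temperature τ. Here x_a is a short decaying trace of recent associative
spikes, so the whole active hidden-state group conditions the next state.

Learning uses two rules. World-model weights follow the STDP rule

    Δw = ζ · s_post(t) · (e^{−w} · s_pre − c),

which potentiates connections from units active in the recent past toward
the fixed point −ln(c) and depresses all others; it runs only during the
learning replay of each experienced (colour, action, feedback) trial.
Goal→associative weights follow a bounded reinforcement rule

    Δw_kg = η · m · ET_k · (w_max − |w_kg|)/w_max · s_g,

with pseudo-reward m = −1 after a planning cycle that simulated the wrong
outcome and m = +1 after real goal achievement; ET marks units that fired.

Per trial the architecture runs planning cycles (15-step forward samples
from the observed colour), computes the mean normalized entropy H of the
associative distributions, and compares it with a threshold
H_Th = ε − f·δ that drops with each failed cycle: it keeps planning while
confident but wrong, acts when the simulated outcome matches the goal, and
hands control to a small softmax exploration network (with
inhibition-of-return learning) when uncertain. Reaction time is the
number of planning cycles.

The task: 20 triplets of the three colours; no mapping exists a priori —
the participant's 2nd/4th/5th response to a dynamically designated colour
(S1/S2/S3) is declared its permanently correct action, fixing the number
of forced errors. A second 60-trial phase switches the goal to "achieve an
incorrect feedback", probing whether the learned world model transfers to
a new goal.

## Worked example

```python
from spikeplan import ModelParams, run_participant, records_frame

result = run_participant(ModelParams(), seed=0, goal_switch=False)
frame = records_frame([result])
block = (frame.triplet - 1) // 5
print(frame.groupby(block).agg(
    p_correct=("feedback", lambda s: (s == "correct").mean()),
    explored=("mode", lambda s: (s == "explored").mean()),
    reaction_time=("reaction_time", "mean"),
).round(2))
```

prints, for seed 0 (blocks of five triplets):

```
         p_correct  explored  reaction_time
triplet
0             0.47      0.47           3.80
1             0.80      0.13           2.53
2             0.47      0.47           4.33
3             0.93      0.00           1.73
```

Early trials are explored (the untrained world model is near maximum
entropy); as contingencies are learned, planning takes over (`explored`
falls), reaction times show the planning effort, and the proportion of
correct feedback rises as established actions are repeated.
`examples/` contains one narrative script per capability: a full session,
the goal switch, emergent generativity (alternative simulated futures from
one stimulus), and the Pearson fitting harness with its random parameter
search. A thin CLI mirrors the library:
`spikeplan run -n 20 -s 0 -o out/`, `spikeplan param-search`,
`spikeplan plot`.

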