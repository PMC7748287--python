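"""The four-layer generative world model.

Architecture: a 10-unit input layer (3 colours, 5 actions, 2 feedback
outcomes), a 2-unit goal layer, a 400-unit recurrent associative layer
(all-to-all, no self-connections) and a 10-unit output layer mirroring the
input layer. The associative layer instantiates the hidden states of a
neural hidden Markov model; its units fire in sequence, one spike per
step, and the output layer reconstructs the observable event predicted by
each hidden state.

Two uses of the same machinery:

* ``planning_cycle`` — forward sampling. The observed colour is clamped on
  the input layer for the first few steps and then released; the goal unit
  stays on; the associative layer free-runs and the output layer samples a
  predicted action and feedback. No weights change.
* ``learn_trial`` — unsupervised replay of the experienced
  colour-action-feedback triple. The input layer is driven by the three
  events in succession, the output layer is clamped to the same events
  (teacher forcing), the associative layer free-runs, and spike-timing-
  dependent plasticity (STDP) shapes the input→associative, recurrent and
  associative→output weights.

Goal→associative weights are learned by a separate reinforcement rule
(``goal_weight_delta``), never by STDP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import arbitration
from .core import LayerParams, LayerState, step_from_drive
from .events import (
    ACTION_UNITS,
    FEEDBACK_UNITS,
    N_EVENTS,
    N_GOALS,
    EventCode,
)
from .params import ModelParams

N_EXPLORE_IN = 6  # 3 colours x 2 goals
N_EXPLORE_OUT = 5  # actions


@dataclass
class WeightSet:
    """All trainable connection matrices plus their learning constants.

    Matrices are stored pre x post. The recurrent matrix keeps a zero
    diagonal at all times; goal weights stay within [-w_max, w_max].
    """

    W_in_assoc: np.ndarray     # (10, n_assoc)
    W_goal_assoc: np.ndarray   # (2, n_assoc)
    W_assoc_assoc: np.ndarray  # (n_assoc, n_assoc), zero diagonal
    W_assoc_out: np.ndarray    # (n_assoc, 10)
    W_explore: np.ndarray      # (6, 5)
    zeta: float
    c: float
    eta: float
    w_max: float
    # per-matrix lower bounds on STDP-trained weights: input (and output)
    # weights encode which contexts a unit codes for — depression must be a
    # hard exclusion, below -cap; recurrent weights encode soft temporal
    # order preferences — a shallow floor lets an input-matched group
    # member outcompete fresh units, closing groups into stable cycles
    floor_in: float = -0.9
    floor_rec: float = -0.4
    floor_out: float = -0.9

    @property
    def stdp_cap(self) -> float:
        """Upper bound on STDP-trained weights: the rule's fixed point -ln(c)."""
        return -np.log(self.c)

    @property
    def n_assoc(self) -> int:
        return self.W_assoc_assoc.shape[0]

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.W_in_assoc.copy(),
            self.W_goal_assoc.copy(),
            self.W_assoc_assoc.copy(),
            self.W_assoc_out.copy(),
            self.W_explore.copy(),
            self.zeta,
            self.c,
            self.eta,
            self.w_max,
            self.floor_in,
            self.floor_rec,
            self.floor_out,
        )

    def check_invariants(self) -> None:
        if np.abs(np.diag(self.W_assoc_assoc)).max() != 0:
            raise AssertionError("recurrent diagonal must stay zero")
        if np.abs(self.W_goal_assoc).max() > self.w_max + 1e-12:
            raise AssertionError("goal weights exceed the w_max bound")


def init_weights(params: ModelParams, rng: np.random.Generator) -> WeightSet:
    """Initial weights with small Gaussian jitter for symmetry breaking.

    All matrices start at zero except the recurrent one, which starts just
    below its depression floor so that once-observed transitions always
    outrank never-observed ones (see the methods note).
    """
    n = params.n_assoc
    sd = params.init_sd

    def jitter(*shape):
        return rng.normal(0.0, sd, size=shape)

    W_aa = params.rec_init + jitter(n, n)
    np.fill_diagonal(W_aa, 0.0)
    return WeightSet(
        W_in_assoc=jitter(N_EVENTS, n),
        W_goal_assoc=np.clip(jitter(N_GOALS, n), -params.w_max, params.w_max),
        W_assoc_assoc=W_aa,
        W_assoc_out=jitter(n, N_EVENTS),
        W_explore=jitter(N_EXPLORE_IN, N_EXPLORE_OUT),
        zeta=params.zeta,
        c=params.c,
        eta=params.eta,
        w_max=params.w_max,
        floor_in=params.stdp_floor_in,
        floor_rec=params.stdp_floor_rec,
        floor_out=params.stdp_floor_out,
    )


@dataclass
class PlanningCycleResult:
    """One forward-sampling run of the world model."""

    assoc_spikes: np.ndarray      # (T, n_assoc) one-hot rows
    out_spikes: np.ndarray        # (T, 10) one-hot rows
    distributions: np.ndarray     # (T, n_assoc) pre-sampling probabilities
    readout_action: EventCode | None
    readout_outcome: EventCode | None
    mean_entropy: float           # normalized over [0, 1]
    fired_units: frozenset[int]   # associative units with >= 1 spike (ET)
    # units that fired after the input clamp was released: the freely
    # sampled part of the trajectory (the cycle's "choice"), used as the
    # eligibility trace when a failed cycle is punished — punishing the
    # stimulus-driven prefix would suppress it for all continuations
    fired_free: frozenset[int] = frozenset()


def _goal_vector(goal: int | None) -> np.ndarray:
    g = np.zeros(N_GOALS)
    if goal is not None:
        if goal not in (0, 1):
            raise ValueError(f"goal must be 0, 1 or None, got {goal}")
        g[goal] = 1.0
    return g


def _assoc_drive(
    weights: WeightSet, input_spikes, goal_spikes, assoc_trace, goal_gain: float = 1.0
) -> np.ndarray:
    # recurrent drive pools the decaying trace of recent spikes, so the
    # whole active hidden-state group (not one spike) conditions the next
    # state; this is what lets context exclusion outweigh input match.
    # the goal term is modulatory: its gain keeps a saturated goal bias
    # decisive between otherwise-tied branches but too weak to override
    # learned structure
    return (
        input_spikes @ weights.W_in_assoc
        + goal_gain * (goal_spikes @ weights.W_goal_assoc)
        + assoc_trace @ weights.W_assoc_assoc
    )


def planning_cycle(
    weights: WeightSet,
    colour: EventCode,
    goal: int | None,
    params: ModelParams,
    rng: np.random.Generator,
) -> PlanningCycleResult:
    """Forward-sample one simulated colour-action-feedback trial.

    The colour drives the associative layer for the first ``clamp_steps``
    steps and is then switched off; the goal unit (if any) stays on for the
    whole cycle; the associative and output layers free-run under
    winner-take-all competition. Weights are never modified.
    """
    if colour.kind != "colour":
        raise ValueError("planning_cycle needs a colour stimulus")
    T, n = params.n_steps, params.n_assoc
    noise = params.noise_sd if params.noise_in_planning else 0.0
    assoc_p = LayerParams(
        n, noise, params.r0, params.tau_r, params.temperature, params.refractory_gain
    )
    # the output layer is a reconstruction readout: no refractory, so the
    # predicted event can fire for its whole duration and dominate counts
    out_p = LayerParams(N_EVENTS, noise, 0.0, params.tau_r, params.temperature)
    assoc = LayerState.fresh(n)
    out = LayerState.fresh(N_EVENTS)
    goal_spikes = _goal_vector(goal)
    colour_vec = colour.one_hot()
    zero_in = np.zeros(N_EVENTS)

    assoc_spikes = np.zeros((T, n))
    out_spikes = np.zeros((T, N_EVENTS))
    dists = np.zeros((T, n))
    trace = np.zeros(n)      # presynaptic trace driving the recurrent term
    read_trace = np.zeros(n)  # slower trace pooled by the output readout
    decay = np.exp(-1.0 / params.epsp_tau)
    rdecay = np.exp(-1.0 / params.readout_tau)
    for t in range(T):
        in_drive = colour_vec if t < params.clamp_steps else zero_in
        u = _assoc_drive(weights, in_drive, goal_spikes, trace, params.goal_gain)
        step_from_drive(assoc, assoc_p, u, rng)
        dists[t] = assoc.distribution
        assoc_spikes[t] = assoc.spike
        # the readout pools decaying excitatory drive from the recently
        # active hidden-state group; a slower decay keeps an event group's
        # evidence alive for its whole duration, so brief trajectory fog
        # cannot outvote it in the spike counts
        step_from_drive(out, out_p, read_trace @ np.maximum(weights.W_assoc_out, 0.0), rng)
        out_spikes[t] = out.spike
        trace = np.maximum(trace * decay, assoc.spike)
        read_trace = np.maximum(read_trace * rdecay, assoc.spike)

    fired = frozenset(np.flatnonzero(assoc_spikes.sum(axis=0) > 0).tolist())
    free = frozenset(
        np.flatnonzero(assoc_spikes[params.clamp_steps :].sum(axis=0) > 0).tolist()
    )
    return PlanningCycleResult(
        assoc_spikes=assoc_spikes,
        out_spikes=out_spikes,
        distributions=dists,
        readout_action=readout(out_spikes, "action", rng),
        readout_outcome=readout(out_spikes, "feedback", rng),
        mean_entropy=arbitration.normalized_entropy(dists),
        fired_units=fired,
        fired_free=free,
    )


def readout(
    out_spikes: np.ndarray,
    category: str,
    rng: np.random.Generator,
) -> EventCode | None:
    """Most frequently fired output event within a category.

    Counts spikes over the cycle within the category's unit range (actions
    or feedback); ties are broken uniformly at random; returns None when no
    spike fell inside the category.
    """
    if category == "action":
        units = ACTION_UNITS
    elif category == "feedback":
        units = FEEDBACK_UNITS
    else:
        raise ValueError(f"unknown readout category {category!r}")
    counts = np.asarray(out_spikes).sum(axis=0)[list(units)]
    if counts.sum() == 0:
        return None
    best = np.flatnonzero(counts == counts.max())
    pick = best[0] if best.size == 1 else rng.choice(best)
    return EventCode.from_unit(units[int(pick)])


def stdp_delta(w: float, s_post: int, s_pre: int, zeta: float, c: float) -> float:
    """Raw STDP increment: zeta * s_post * (exp(-w) * s_pre - c).

    Gated by the post spike; potentiates towards the fixed point -ln(c)
    when the pre unit fired one step earlier, otherwise depresses by
    zeta * c.
    """
    return zeta * s_post * (np.exp(-w) * s_pre - c)


def stdp_apply(
    w: float, s_post: int, s_pre: int, zeta: float, c: float, floor: float = -0.6
) -> float:
    """Updated weight after one STDP step, bounded to [floor, -ln(c)].

    The cap is the rule's own potentiation fixed point, so persistent
    co-firing converges to it monotonically from below; the floor keeps
    the exponential potentiation term finite for long-depressed weights.
    """
    return float(np.clip(w + stdp_delta(w, s_post, s_pre, zeta, c), floor, -np.log(c)))


def _stdp_column(
    W: np.ndarray, pre_vec: np.ndarray, post_idx: int, zeta: float, c: float, floor: float
) -> None:
    # one-spike-per-layer: only the firing post unit's incoming column moves
    col = W[:, post_idx]
    np.clip(col + zeta * (np.exp(-col) * pre_vec - c), floor, -np.log(c), out=col)


def learn_trial(
    weights: WeightSet,
    colour: EventCode,
    action: EventCode,
    outcome: EventCode,
    goal: int | None,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[WeightSet, frozenset[int]]:
    """Replay one experienced trial and apply STDP; mutates ``weights``.

    The 15 steps are split evenly between the three events: the input
    layer drives the associative layer with the colour, then the executed
    action, then the observed feedback; the output layer is clamped to the
    same events one step later (teacher forcing, matching the one-step
    associative→output lag); the associative layer free-runs. STDP updates
    input→associative, recurrent and associative→output weights; the
    recurrent diagonal is re-zeroed after every update; goal weights are
    untouched. Returns the weights and the set of associative units that
    fired during the replay (the eligibility trace of the trial).
    """
    if colour.kind != "colour" or action.kind != "action" or outcome.kind != "feedback":
        raise ValueError("learn_trial needs (colour, action, feedback) events")
    T, n = params.n_steps, params.n_assoc
    third = T // 3
    noise = params.noise_sd if params.noise_in_learning else 0.0
    assoc_p = LayerParams(
        n, noise, params.r0, params.tau_r, params.temperature, params.refractory_gain
    )
    assoc = LayerState.fresh(n)
    goal_spikes = (
        _goal_vector(goal) if params.goal_drive_in_learning else _goal_vector(None)
    )

    schedule = [colour] * third + [action] * third + [outcome] * (T - 2 * third)
    drive_in = np.stack([e.one_hot() for e in schedule])
    # output teacher signal lags the drive by one step (input -> assoc -> out)
    out_clamp = np.vstack([drive_in[:1], drive_in[:-1]])

    trace = np.zeros(n)
    decay = np.exp(-1.0 / params.epsp_tau)
    spikes = np.zeros((T, n))
    fired = np.zeros(n, dtype=bool)
    W = params.stdp_window
    for t in range(T):
        u = _assoc_drive(weights, drive_in[t], goal_spikes, trace, params.goal_gain)
        step_from_drive(assoc, assoc_p, u, rng)
        k = int(np.argmax(assoc.spike))
        fired[k] = True
        o = int(out_clamp[t].argmax())
        # recurrent and output plasticity treat every unit that fired in the
        # recent window as presynaptic, wiring the whole preceding event
        # group (not just one spike) to its successors and to the readout
        recent = (spikes[max(0, t - W) : t].sum(axis=0) > 0).astype(float)

        zc = weights.zeta
        _stdp_column(weights.W_in_assoc, drive_in[t], k, zc, weights.c, weights.floor_in)
        _stdp_column(weights.W_assoc_assoc, recent, k, zc, weights.c, weights.floor_rec)
        weights.W_assoc_assoc[k, k] = 0.0
        _stdp_column(weights.W_assoc_out, recent, o, zc, weights.c, weights.floor_out)

        spikes[t] = assoc.spike
        trace = np.maximum(trace * decay, assoc.spike)

    return weights, frozenset(np.flatnonzero(fired).tolist())


def goal_weight_delta(
    w_kg: float, m: int, ET_k: int, s_g: int, eta: float, w_max: float
) -> float:
    """Reinforcement increment for one goal→associative weight.

    eta * m * ET_k * ((w_max - |w|)/w_max) * s_g, with m = +1 on goal
    achievement in the environment and m = -1 after a failed planning
    cycle. The soft bound factor vanishes at |w| = w_max.
    """
    if m not in (-1, 1):
        raise ValueError("pseudo-reward m must be -1 or +1")
    if abs(w_kg) > w_max + 1e-12:
        raise ValueError("goal weight outside [-w_max, w_max] on entry")
    return eta * m * ET_k * ((w_max - abs(w_kg)) / w_max) * s_g


def update_goal_weights(
    weights: WeightSet,
    fired_units,
    m: int,
    goal: int | None,
) -> WeightSet:
    """Apply the reinforcement rule to the active goal's weight row.

    ``fired_units`` is the eligibility trace: the associative units that
    fired at least once during the relevant planning cycle or trial (a
    PlanningCycleResult may be passed directly). Silent units and the
    inactive goal's row are untouched; results are clipped to the bound.
    """
    if m not in (-1, 1):
        raise ValueError("pseudo-reward m must be -1 or +1")
    if goal is None:
        return weights
    if hasattr(fired_units, "fired_units"):
        fired_units = fired_units.fired_units
    idx = np.fromiter(fired_units, dtype=np.int64)
    if idx.size == 0:
        return weights
    row = weights.W_goal_assoc[goal]
    w = row[idx]
    row[idx] = np.clip(
        w + weights.eta * m * (weights.w_max - np.abs(w)) / weights.w_max,
        -weights.w_max,
        weights.w_max,
    )
    return weights


# ---------------------------------------------------------------------------
# serialization and diagnostics


_MATRICES = ("W_in_assoc", "W_goal_assoc", "W_assoc_assoc", "W_assoc_out", "W_explore")


def save_weights(weights: WeightSet, path, extra_meta: dict | None = None) -> None:
    """Write all matrices plus a metadata record to one .npz archive."""
    meta = {
        "zeta": weights.zeta,
        "c": weights.c,
        "eta": weights.eta,
        "w_max": weights.w_max,
        "floor_in": weights.floor_in,
        "floor_rec": weights.floor_rec,
        "floor_out": weights.floor_out,
    }
    if extra_meta:
        meta.update(extra_meta)
    arrays = {name: getattr(weights, name) for name in _MATRICES}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_weights(path) -> WeightSet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        return WeightSet(
            *(data[name].copy() for name in _MATRICES),
            zeta=float(meta["zeta"]),
            c=float(meta["c"]),
            eta=float(meta["eta"]),
            w_max=float(meta["w_max"]),
            floor_in=float(meta.get("floor_in", -0.9)),
            floor_rec=float(meta.get("floor_rec", -0.2)),
            floor_out=float(meta.get("floor_out", -0.9)),
        )


def spikes_to_frame(cycle: PlanningCycleResult):
    """Tidy (step, layer, unit) table of one cycle's spikes, for rasters."""
    import pandas as pd

    rows = []
    for layer, spikes in (("assoc", cycle.assoc_spikes), ("output", cycle.out_spikes)):
        steps, units = np.nonzero(spikes)
        rows.append(pd.DataFrame({"step": steps, "layer": layer, "unit": units}))
    return pd.concat(rows, ignore_index=True).sort_values(
        ["step", "layer"], ignore_index=True
    )
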