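"""End-to-end sessions, behavioural aggregation and model fitting.

A trial loops planning cycles under the arbitration rule, executes the
chosen action in the task, always replays the experienced triple through
the STDP learning rule, and applies the goal / exploration reinforcement
updates. A participant is 60 trials pursuing 'correct feedback' followed
(optionally) by 60 trials pursuing 'incorrect feedback' with the same
world model and the same established colour-action contingencies.

Aggregation produces the standard behavioural curves: per-stimulus
per-triplet correct proportions, and reaction times (planning-cycle
counts) aligned on 'representative steps' that separate each stimulus's
exploration trials (steps 1-5) from its exploitation trials (step 6 on).
A Pearson-correlation fitness against user-supplied reference curves and
a random parameter search close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arbitration import ArbitrationParams, arbitrate
from .events import GOAL_CORRECT, GOAL_INCORRECT, EventCode
from .exploration import ExplorationParams, punish_exploration, select_exploration_action
from .model import (
    WeightSet,
    init_weights,
    learn_trial,
    planning_cycle,
    update_goal_weights,
)
from .params import SEARCH_RANGES, ModelParams
from .task import TaskState, goal_achieved, respond

GOAL_NAMES = {GOAL_CORRECT: "correct", GOAL_INCORRECT: "incorrect"}
STIMULI = ("S1", "S2", "S3")

# representative-step alignment: each stimulus's successive trials map onto
# a common axis whose steps 1-5 hold the staircased exploration responses
# (2 for S1, 4 for S2, 5 for S3) and whose steps from 6 hold exploitation
_REP_HEADS = {"S1": [1, 2], "S2": [1, 2, 3, 4], "S3": [1, 2, 3, 4, 5]}


def representative_steps(label: str, n_trials: int = 20) -> list[int]:
    head = _REP_HEADS[label]
    tail = list(range(6, 6 + n_trials - len(head)))
    return head + tail


@dataclass
class TrialRecord:
    trial: int              # 0-based index across the whole session
    phase: int              # 1 = 'correct feedback' goal, 2 = switched goal
    triplet: int            # 1-based triplet index within the phase
    colour: int             # colour index 1-3
    goal: int               # goal index
    mode: str               # 'planned' or 'explored'
    action: int             # action index 1-5
    feedback: str           # 'correct' or 'incorrect'
    achieved: bool          # feedback matched the goal
    reaction_time: int      # planning cycles executed
    entropy: float          # normalized entropy of the deciding cycle
    label: str | None = None  # S1/S2/S3, filled once designations are known


@dataclass
class ParticipantResult:
    records: list[TrialRecord]
    weights: WeightSet
    task: TaskState
    seed: int


def run_trial(
    weights: WeightSet,
    task_state: TaskState,
    colour: EventCode,
    goal: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> TrialRecord:
    """One full trial: plan/arbitrate, act, learn. Mutates weights and task.

    Failed planning cycles apply the m = -1 goal update before replanning;
    the executed action always triggers the STDP replay; goal success adds
    the m = +1 goal update (eligibility from the successful cycle, or from
    the replay when the action came from exploration); failure punishes the
    exploration weights.
    """
    arb = ArbitrationParams(params.epsilon, params.delta, params.max_cycles)
    expl = ExplorationParams(params.temperature, params.eta, params.w_max)

    f = 0
    while True:
        cycle = planning_cycle(weights, colour, goal, params, rng)
        outcome = cycle.readout_outcome if cycle.readout_action is not None else None
        decision = arbitrate(cycle.mean_entropy, f, outcome, goal, arb)
        if decision.mode == "replan":
            if outcome is not None:
                # punish only the freely sampled part of a definitely wrong
                # trajectory; the stimulus-driven prefix fires in every
                # cycle regardless of the choice, and a cycle that read out
                # no event sequence identified nothing to punish
                update_goal_weights(weights, cycle.fired_free, -1, goal)
            f += 1
            continue
        break

    if decision.mode == "act_planned":
        mode = "planned"
        action = cycle.readout_action
    else:
        mode = "explored"
        action = select_exploration_action(weights.W_explore, colour, goal, expl, rng)

    trial_index = task_state.trial_index
    feedback, _ = respond(task_state, colour, action)
    achieved = goal_achieved(feedback, goal)

    _, replay_fired = learn_trial(weights, colour, action, feedback, goal, params, rng)
    if achieved:
        trace = cycle.fired_units if mode == "planned" else replay_fired
        update_goal_weights(weights, trace, +1, goal)
    else:
        punish_exploration(weights.W_explore, colour, goal, action, expl)

    return TrialRecord(
        trial=trial_index,
        phase=1,  # caller overwrites for the switched-goal phase
        triplet=trial_index // 3 + 1,
        colour=colour.index,
        goal=goal,
        mode=mode,
        action=action.index,
        feedback="correct" if feedback.index == 1 else "incorrect",
        achieved=achieved,
        reaction_time=f + 1,
        entropy=decision.entropy,
    )


def run_participant(
    params: ModelParams, seed: int, goal_switch: bool = True
) -> ParticipantResult:
    """Simulate one participant; fully reproducible from (params, seed).

    Phase 1: 60 trials with the goal 'achieve a correct feedback'. Phase 2
    (if ``goal_switch``): 60 further trials on a fresh triplet schedule with
    the goal 'achieve an incorrect feedback', keeping the learned weights
    and the established colour-action contingencies.
    """
    rng = np.random.default_rng(seed)
    weights = init_weights(params, rng)
    task = TaskState.new_session(rng, params.n_triplets)

    phases = [(1, GOAL_CORRECT)]
    if goal_switch:
        phases.append((2, GOAL_INCORRECT))

    records: list[TrialRecord] = []
    for phase, goal in phases:
        if phase == 2:
            task.extend_session(rng, params.n_triplets)
        start = task.trial_index
        for _ in range(params.n_trials_per_goal):
            colour = task.current_colour
            rec = run_trial(weights, task, colour, goal, params, rng)
            rec.phase = phase
            rec.triplet = (rec.trial - start) // 3 + 1
            records.append(rec)

    for rec in records:  # designations are complete after triplet 5
        rec.label = task.designation.get(rec.colour)
    return ParticipantResult(records=records, weights=weights, task=task, seed=seed)


def records_frame(results: list[ParticipantResult]) -> pd.DataFrame:
    """Tidy one-row-per-trial table over participants."""
    rows = []
    for res in results:
        for r in res.records:
            rows.append(
                {
                    "participant": res.seed,
                    "trial": r.trial,
                    "phase": r.phase,
                    "triplet": r.triplet,
                    "colour": r.colour,
                    "label": r.label,
                    "goal": GOAL_NAMES[r.goal],
                    "mode": r.mode,
                    "action": r.action,
                    "feedback": r.feedback,
                    "achieved": r.achieved,
                    "reaction_time": r.reaction_time,
                    "entropy": r.entropy,
                }
            )
    return pd.DataFrame(rows)


def _sem(x: pd.Series) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def aggregate_performance(
    frame: pd.DataFrame, phase: int = 1, metric: str = "correct"
) -> pd.DataFrame:
    """Per-stimulus per-triplet mean +/- SE over participants.

    ``metric='correct'`` scores correct feedback (the learning curves);
    ``metric='achieved'`` scores goal achievement (the goal-switch view).
    """
    sub = frame[frame["phase"] == phase].copy()
    if metric == "correct":
        sub["value"] = (sub["feedback"] == "correct").astype(float)
    elif metric == "achieved":
        sub["value"] = sub["achieved"].astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    grouped = (
        sub.groupby(["label", "triplet"])["value"]
        .agg(mean="mean", se=_sem, n="count")
        .reset_index()
    )
    return grouped


def aggregate_rt(frame: pd.DataFrame, phase: int = 1) -> pd.DataFrame:
    """Mean reaction time (planning cycles) per representative step.

    Each stimulus's successive trials within the phase map onto its
    representative-step list; contributions are averaged over stimuli and
    participants per step.
    """
    sub = frame[frame["phase"] == phase]
    rows = []
    for (participant, label), grp in sub.groupby(["participant", "label"]):
        if label not in STIMULI:
            continue
        grp = grp.sort_values("trial")
        steps = representative_steps(label, len(grp))
        for step, rt in zip(steps, grp["reaction_time"]):
            rows.append({"participant": participant, "label": label, "step": step, "rt": rt})
    long = pd.DataFrame(rows)
    return (
        long.groupby("step")["rt"].agg(mean="mean", se=_sem, n="count").reset_index()
    )


@dataclass
class CurveSet:
    """The four behavioural datasets used for fitting."""

    performance: dict[str, np.ndarray]  # label -> per-triplet correct proportion
    rt: pd.Series                       # representative step -> mean reaction time

    def __post_init__(self) -> None:
        for label, curve in self.performance.items():
            curve = np.asarray(curve, dtype=float)
            if ((curve < 0) | (curve > 1)).any():
                raise ValueError(f"{label} proportions outside [0, 1]")
            self.performance[label] = curve
        if (np.asarray(self.rt, dtype=float) < 0).any():
            raise ValueError("reaction times must be >= 0")


def model_curves(frame: pd.DataFrame, phase: int = 1) -> CurveSet:
    perf = aggregate_performance(frame, phase=phase)
    curves = {
        label: grp.sort_values("triplet")["mean"].to_numpy()
        for label, grp in perf.groupby("label")
    }
    rt = aggregate_rt(frame, phase=phase).set_index("step")["mean"]
    return CurveSet(performance=curves, rt=rt)


def pearson(model_curve: np.ndarray, reference_curve: np.ndarray) -> float:
    """Pearson correlation R = C_dm / sqrt(V_d * V_m)."""
    a = np.asarray(model_curve, dtype=float)
    b = np.asarray(reference_curve, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("curves must share a length of at least 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance curve")
    return float(stats.pearsonr(a, b).statistic)


def _participant_seeds(rng: np.random.Generator, n: int) -> list[int]:
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def fitness(
    params: ModelParams,
    reference: CurveSet,
    n_participants: int,
    rng: np.random.Generator,
) -> float:
    """Mean Pearson correlation between model and reference curves.

    Runs ``n_participants`` first-phase sessions, averages the behaviour,
    and correlates the three per-stimulus performance curves and the
    reaction-time curve (on the representative steps both sides define)
    against the reference; the four coefficients are averaged.
    """
    results = [
        run_participant(params, seed, goal_switch=False)
        for seed in _participant_seeds(rng, n_participants)
    ]
    curves = model_curves(records_frame(results))
    rs = []
    for label in STIMULI:
        rs.append(pearson(curves.performance[label], reference.performance[label]))
    common = curves.rt.index.intersection(reference.rt.index)
    rs.append(pearson(curves.rt.loc[common].to_numpy(), reference.rt.loc[common].to_numpy()))
    return float(np.mean(rs))


def sample_params(
    rng: np.random.Generator, ranges: dict[str, tuple[float, float]] | None = None
) -> ModelParams:
    """Uniform draw of the seven searchable parameters within their ranges."""
    ranges = dict(SEARCH_RANGES, **(ranges or {}))
    draw = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    return ModelParams(**draw)


def parameter_search(
    ranges: dict[str, tuple[float, float]] | None,
    n_combos: int,
    n_participants: int,
    reference: CurveSet,
    rng: np.random.Generator,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Random parameter search, ranked by fitness (best first).

    Deterministic and partitionable: each combo's sampling and evaluation
    use an RNG derived from a master seed and the combo index, so the work
    can be split across processes without changing the result.
    """
    master = int(rng.integers(0, 2**31 - 1))

    def evaluate(i: int) -> dict:
        p = sample_params(np.random.default_rng([master, i, 0]), ranges)
        fit = fitness(p, reference, n_participants, np.random.default_rng([master, i, 1]))
        return {"combo": i, "fitness": fit, **{k: getattr(p, k) for k in SEARCH_RANGES}}

    if n_jobs == 1:
        rows = [evaluate(i) for i in range(n_combos)]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(evaluate)(i) for i in range(n_combos))
    return (
        pd.DataFrame(rows)
        .sort_values("fitness", ascending=False, ignore_index=True)
    )
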