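"""Two-layer stochastic exploration component.

Six input units encode the colour x goal combinations; five output units
encode the actions. When planning is abandoned, the single input unit
matching the current (colour, goal) is activated, the output potentials
are its weight row, and an action is sampled from a softmax with
temperature tau. Learning is punishment-only: an action that failed the
goal has its weight to the active input lowered by the same bounded
reinforcement rule used for the goal layer, implementing an
inhibition-of-return over actions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import competitive_distribution, sample_spike
from .events import N_COLOURS, N_GOALS, EventCode


@dataclass(frozen=True)
class ExplorationParams:
    temperature: float  # softmax temperature, > 0
    eta: float          # learning rate (shared with the goal rule)
    w_max: float = 0.5  # weight bound (shared)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def _input_index(colour: EventCode, goal: int) -> int:
    if colour.kind != "colour":
        raise ValueError("exploration needs a colour stimulus")
    if goal not in range(N_GOALS):
        raise ValueError(f"invalid goal index {goal}")
    return (colour.index - 1) * N_GOALS + goal


def action_probabilities(
    W_explore: np.ndarray, colour: EventCode, goal: int, params: ExplorationParams
) -> np.ndarray:
    """Softmax selection probabilities over the five actions."""
    potentials = W_explore[_input_index(colour, goal)]
    return competitive_distribution(potentials / params.temperature)


def select_exploration_action(
    W_explore: np.ndarray,
    colour: EventCode,
    goal: int,
    params: ExplorationParams,
    rng: np.random.Generator,
) -> EventCode:
    """Sample an action for the active (colour, goal) input unit."""
    probs = action_probabilities(W_explore, colour, goal, params)
    spike = sample_spike(probs, rng)
    return EventCode("action", int(np.argmax(spike)) + 1)


def punish_exploration(
    W_explore: np.ndarray,
    colour: EventCode,
    goal: int,
    action: EventCode,
    params: ExplorationParams,
) -> np.ndarray:
    """Lower the weight of an action that failed the goal; mutates in place.

    Applies the bounded reinforcement rule with m = -1 to the single
    connection from the active (colour, goal) unit to the chosen action;
    every other weight is untouched. Called only after a failed executed
    action (success never trains the component).
    """
    if action.kind != "action":
        raise ValueError("punish_exploration needs an action event")
    i = _input_index(colour, goal)
    j = action.index - 1
    w = W_explore[i, j]
    w = w - params.eta * (params.w_max - abs(w)) / params.w_max
    W_explore[i, j] = np.clip(w, -params.w_max, params.w_max)
    return W_explore
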