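"""Event codes shared by the input and output layers.

The observable world of the visuomotor task consists of ten events: three
colour stimuli, five button-press actions, and two feedback outcomes
(correct / incorrect). Each event owns one fixed unit index in the
ten-neuron input layer, and the identically structured output layer reuses
the same mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_EVENTS = 10
N_COLOURS = 3
N_ACTIONS = 5
N_FEEDBACK = 2

# unit index ranges (0-based, half-open) within the 10-unit layers
COLOUR_UNITS = range(0, 3)
ACTION_UNITS = range(3, 8)
FEEDBACK_UNITS = range(8, 10)

KINDS = ("colour", "action", "feedback")

# goal indices
GOAL_CORRECT = 0
GOAL_INCORRECT = 1
N_GOALS = 2


@dataclass(frozen=True)
class EventCode:
    """One observable event with its fixed layer-unit index.

    ``index`` is 1-based within its kind: colours 1-3, actions 1-5,
    feedback 1 = correct, 2 = incorrect.
    """

    kind: str
    index: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        limits = {"colour": N_COLOURS, "action": N_ACTIONS, "feedback": N_FEEDBACK}
        if not 1 <= self.index <= limits[self.kind]:
            raise ValueError(f"{self.kind} index {self.index} out of range")

    @property
    def unit(self) -> int:
        """0-based unit index in the 10-unit input/output layers."""
        offset = {"colour": 0, "action": 3, "feedback": 8}[self.kind]
        return offset + self.index - 1

    def one_hot(self) -> np.ndarray:
        v = np.zeros(N_EVENTS)
        v[self.unit] = 1.0
        return v

    @staticmethod
    def from_unit(unit: int) -> "EventCode":
        if unit in COLOUR_UNITS:
            return EventCode("colour", unit + 1)
        if unit in ACTION_UNITS:
            return EventCode("action", unit - 3 + 1)
        if unit in FEEDBACK_UNITS:
            return EventCode("feedback", unit - 8 + 1)
        raise ValueError(f"unit {unit} outside the 10-unit layer")


def colour(i: int) -> EventCode:
    return EventCode("colour", i)


def action(i: int) -> EventCode:
    return EventCode("action", i)


CORRECT = EventCode("feedback", 1)
INCORRECT = EventCode("feedback", 2)


def feedback_for_goal(goal: int) -> EventCode:
    """The feedback outcome that satisfies a goal index."""
    if goal == GOAL_CORRECT:
        return CORRECT
    if goal == GOAL_INCORRECT:
        return INCORRECT
    raise ValueError(f"goal must be {GOAL_CORRECT} or {GOAL_INCORRECT}, got {goal}")
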