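"""The visuomotor staircase task.

Three colours are shown in pseudo-random triplets (each triplet a
permutation of the three colours); the participant answers each with one
of five button presses. No colour-action mapping exists a priori: the
correct action for each colour is established dynamically so that every
participant experiences a fixed error staircase. The first response inside
the second triplet whose colour has no established action designates that
colour S1 and declares that very response correct (the colour's 2nd
response overall); likewise the fourth triplet designates S2 (4th
response) and the fifth triplet designates S3 (5th response). Once
established, a colour's correct action never changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import CORRECT, INCORRECT, N_COLOURS, EventCode, colour as colour_event

# 0-based triplet index -> stimulus label designated by that triplet
DESIGNATION_TRIPLETS = {1: "S1", 3: "S2", 4: "S3"}


def generate_schedule(
    rng: np.random.Generator, n_triplets: int = 20
) -> list[EventCode]:
    """Pseudo-random stimulus order: independent colour permutations per triplet."""
    schedule: list[EventCode] = []
    for _ in range(n_triplets):
        schedule.extend(colour_event(i + 1) for i in rng.permutation(N_COLOURS))
    return schedule


@dataclass
class TaskState:
    """Per-session staircase bookkeeping."""

    schedule: list[EventCode]
    response_count: dict[int, int] = field(
        default_factory=lambda: {i: 0 for i in range(1, N_COLOURS + 1)}
    )
    designation: dict[int, str] = field(default_factory=dict)  # colour -> label
    correct_action: dict[int, EventCode] = field(default_factory=dict)
    trial_index: int = 0
    # per-colour actions that have already drawn an incorrect feedback
    failed_actions: dict[int, set[int]] = field(
        default_factory=lambda: {i: set() for i in range(1, N_COLOURS + 1)}
    )
    # trials where the designating response coincided with an action the
    # participant had already seen fail for that colour (declared correct
    # anyway, but logged)
    collisions: list[int] = field(default_factory=list)

    @staticmethod
    def new_session(rng: np.random.Generator, n_triplets: int = 20) -> "TaskState":
        return TaskState(schedule=generate_schedule(rng, n_triplets))

    @property
    def current_colour(self) -> EventCode:
        return self.schedule[self.trial_index]

    @property
    def finished(self) -> bool:
        return self.trial_index >= len(self.schedule)

    def extend_session(self, rng: np.random.Generator, n_triplets: int = 20) -> None:
        """Append a fresh block of triplets (e.g. for the goal-switch phase).

        Established correct actions and designations persist; no new
        designations can occur past the fifth triplet of the session.
        """
        self.schedule = list(self.schedule) + generate_schedule(rng, n_triplets)

    def label_of(self, colour: EventCode) -> str | None:
        return self.designation.get(colour.index)


def respond(
    state: TaskState, colour: EventCode, action: EventCode
) -> tuple[EventCode, TaskState]:
    """Execute one response; returns the feedback and the mutated state.

    Feedback is correct iff the colour already has (or acquires, via the
    designation rule) an established correct action equal to the response.
    """
    if state.finished:
        raise RuntimeError("session schedule exhausted")
    if colour != state.current_colour:
        raise ValueError(
            f"out-of-order response: expected {state.current_colour}, got {colour}"
        )
    if action.kind != "action":
        raise ValueError("response must be an action event")

    state.response_count[colour.index] += 1
    triplet = state.trial_index // 3
    label = DESIGNATION_TRIPLETS.get(triplet)
    if (
        label is not None
        and label not in state.designation.values()
        and colour.index not in state.correct_action
    ):
        # the designating response itself is declared correct, whatever it is
        state.designation[colour.index] = label
        state.correct_action[colour.index] = action
        if action.index in state.failed_actions[colour.index]:
            state.collisions.append(state.trial_index)

    established = state.correct_action.get(colour.index)
    feedback = CORRECT if established is not None and action == established else INCORRECT
    if feedback == INCORRECT:
        state.failed_actions[colour.index].add(action.index)
    state.trial_index += 1
    return feedback, state


def goal_achieved(feedback: EventCode, goal: int) -> bool:
    """True iff the feedback outcome is the one the goal targets."""
    from .events import feedback_for_goal

    return feedback == feedback_for_goal(goal)
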