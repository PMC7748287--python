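import numpy as np
import pytest

from spikeplan import ModelParams, WeightSet
from spikeplan.events import N_EVENTS


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def build_chain_weights(
    params: ModelParams,
    colour_idx: int = 1,
    action_idx: int = 3,
    outcome_correct: bool = True,
    strong: float = 5.0,
    weak: float = -5.0,
) -> WeightSet:
    """Hand-built deterministic world model: one rigid 15-step chain.

    Dedicated units 0..14 fire in order; units 0-4 code the colour phase,
    5-9 the action phase, 10-14 the feedback phase; output links map each
    phase to its event. All other weights are strongly negative, so the
    trajectory and readout are deterministic up to membrane noise.
    """
    from spikeplan.events import EventCode, colour as colour_event

    n = params.n_assoc
    W_in = np.full((N_EVENTS, n), weak)
    W_goal = np.zeros((2, n))
    W_aa = np.full((n, n), weak)
    np.fill_diagonal(W_aa, 0.0)
    W_out = np.full((n, N_EVENTS), weak)

    chain = list(range(15))
    col_unit = colour_event(colour_idx).unit
    act_unit = EventCode("action", action_idx).unit
    fb_unit = EventCode("feedback", 1 if outcome_correct else 2).unit
    for t, u in enumerate(chain):
        if t < 5:
            W_in[col_unit, u] = strong
            W_out[u, col_unit] = strong
        elif t < 10:
            W_out[u, act_unit] = strong
        else:
            W_out[u, fb_unit] = strong
        if t > 0:
            W_aa[chain[t - 1], u] = strong
            W_aa[u, u] = 0.0
    return WeightSet(
        W_in_assoc=W_in,
        W_goal_assoc=W_goal,
        W_assoc_assoc=W_aa,
        W_assoc_out=W_out,
        W_explore=np.zeros((6, 5)),
        zeta=params.zeta,
        c=params.c,
        eta=params.eta,
        w_max=params.w_max,
    )


class IdealAgent:
    """Never repeats an error for a colour; always repeats a discovered
    correct action."""

    def __init__(self) -> None:
        self.known: dict[int, int] = {}
        self.failed: dict[int, set[int]] = {}

    def choose(self, colour_idx: int) -> int:
        if colour_idx in self.known:
            return self.known[colour_idx]
        tried = self.failed.setdefault(colour_idx, set())
        return next(a for a in range(1, 6) if a not in tried)

    def observe(self, colour_idx: int, action_idx: int, correct: bool) -> None:
        if correct:
            self.known[colour_idx] = action_idx
        else:
            self.failed.setdefault(colour_idx, set()).add(action_idx)
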