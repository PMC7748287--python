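"""Model parameters and architecture constants.

The seven searchable parameters (STDP learning rate and threshold, the
goal/exploration learning rate, exploration softmax temperature, membrane
noise, and the entropy-threshold start and decrement) default to the
best-fitting values found by random search; the remaining fields are fixed
architecture constants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

# allowed search range per searchable parameter
SEARCH_RANGES: dict[str, tuple[float, float]] = {
    "zeta": (0.1, 1.0),
    "c": (0.1, 1.0),
    "eta": (0.001, 1.0),
    "temperature": (0.01, 0.1),
    "noise_sd": (0.01, 0.1),
    "epsilon": (0.3, 1.0),
    "delta": (0.01, 0.2),
}


@dataclass
class ModelParams:
    # searchable parameters (defaults: fitted values)
    zeta: float = 0.96        # STDP learning rate
    c: float = 0.67           # STDP depression threshold, in (0, 1)
    eta: float = 0.008        # goal / exploration learning rate
    temperature: float = 0.02  # exploration softmax temperature
    noise_sd: float = 0.02    # membrane-potential Gaussian noise sd
    epsilon: float = 0.74     # entropy threshold at trial start
    delta: float = 0.12       # per-failed-cycle threshold decrement

    # fixed architecture constants
    n_assoc: int = 400        # associative-layer size
    n_steps: int = 15         # steps per trial / planning cycle
    clamp_steps: int = 5      # initial steps the colour is clamped
    r0: float = 1.1           # refractory amplitude
    tau_r: float = 9.5        # refractory decay constant (steps)
    w_max: float = 0.5        # goal / exploration weight bound
    n_triplets: int = 20      # colour triplets per goal phase
    max_cycles: int = 50      # hard safety cap on planning cycles
    init_sd: float = 0.01     # weight-initialisation jitter sd
    # lower bounds on STDP-trained weights, per matrix (see methods note):
    # input/output depression is a hard context exclusion (below -ln(c));
    # recurrent depression is a soft order preference (above -(ln(1/c)))
    stdp_floor_in: float = -0.9
    stdp_floor_rec: float = -0.4
    stdp_floor_out: float = -0.9
    # presynaptic window (steps): a unit counts as "pre" for recurrent and
    # output plasticity if it fired within this many recent steps, so a
    # whole event group, not just the single previous spike, gets wired to
    # its successors; matches the event duration (= clamp_steps)
    stdp_window: int = 5
    # decay constant (steps) of the presynaptic trace pooled by the
    # associative recurrent drive; short, so the current event group
    # dominates the next-state competition
    epsp_tau: float = 1.25
    # decay constant of the trace the output readout pools; longer, so an
    # event group's evidence persists for its whole duration and brief
    # trajectory fog cannot outvote it in the spike counts
    readout_tau: float = 1.25
    # recurrent weights start just below the recurrent floor: a transition
    # once observed and later depressed still outranks one never observed,
    # so hidden-state groups serving several contexts keep weak links to
    # all learned predecessors instead of only the most recent one
    rec_init: float = -0.5
    # scale on the refractory subtraction inside the tempered competition:
    # large enough to force distinct units at event onset, small enough
    # that an exhausted event group re-fires its own members rather than
    # recruiting fresh units at the phase tail
    refractory_gain: float = 1.0
    # gain on the goal->associative drive: a saturated goal bias should
    # decide between otherwise-tied branches, not override learned structure
    goal_gain: float = 0.15
    noise_in_planning: bool = True  # apply membrane noise during planning
    noise_in_learning: bool = True  # and during the learning replay
    goal_drive_in_learning: bool = True  # goal unit clamped on in replay

    def __post_init__(self) -> None:
        if not 0 < self.c < 1:
            raise ValueError("c must lie in (0, 1)")
        if self.zeta <= 0 or self.eta <= 0 or self.temperature <= 0:
            raise ValueError("zeta, eta and temperature must be positive")
        if self.noise_sd < 0 or self.delta <= 0:
            raise ValueError("noise_sd must be >= 0 and delta > 0")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")

    @property
    def n_trials_per_goal(self) -> int:
        return 3 * self.n_triplets

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
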