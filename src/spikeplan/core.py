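"""Discrete-time stochastic winner-take-all spiking layer.

Each layer holds one membrane potential per unit. At every step a unit's
potential is the weighted sum of the spikes arriving from the previous
step, minus an exponentially decaying refractory term indexed from the
unit's own last spike, plus optional i.i.d. Gaussian noise. Lateral
inhibition is abstracted by a softmax over the potentials, which turns the
layer into a categorical distribution from which exactly one spike per
step is sampled (winner-take-all). Clamped layers (input, goal) bypass the
competition and simply impose a binary pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# sentinel for "this unit has never spiked"
NEVER = -1


@dataclass
class LayerParams:
    """Constants of one winner-take-all layer.

    noise_sd is the standard deviation of per-step Gaussian potential
    noise; r0 and tau_r set the refractory subtraction r0*exp(-age/tau_r),
    with age counted in steps since the unit's own last spike.
    """

    n_units: int
    noise_sd: float = 0.0
    r0: float = 1.1
    tau_r: float = 9.5
    temperature: float = 1.0  # inverse sharpness of the competition
    refractory_gain: float = 1.0  # scale on the refractory subtraction
    v_scale: float = 1.0  # total layer firing constant; fixed to 1

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.r0 < 0:
            raise ValueError("r0 must be >= 0")
        if self.tau_r <= 0:
            raise ValueError("tau_r must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class LayerState:
    """Mutable per-step state of a layer."""

    potentials: np.ndarray
    last_spike_age: np.ndarray  # NEVER for units that have not fired
    spike: np.ndarray
    distribution: np.ndarray | None = None  # pre-sampling probabilities

    @staticmethod
    def fresh(n_units: int) -> "LayerState":
        return LayerState(
            potentials=np.zeros(n_units),
            last_spike_age=np.full(n_units, NEVER, dtype=np.int64),
            spike=np.zeros(n_units),
        )


def total_activation(weight_rows: np.ndarray, incoming_spikes: np.ndarray) -> np.ndarray:
    """Summed synaptic drive per target unit.

    ``weight_rows`` has one row per target unit and one column per source
    unit; ``incoming_spikes`` is the concatenated binary spike vector of
    the source layers from the previous step.
    """
    weight_rows = np.asarray(weight_rows, dtype=float)
    incoming_spikes = np.asarray(incoming_spikes, dtype=float)
    if weight_rows.shape[-1] != incoming_spikes.shape[0]:
        raise ValueError(
            f"weight columns ({weight_rows.shape[-1]}) do not match "
            f"source spikes ({incoming_spikes.shape[0]})"
        )
    return weight_rows @ incoming_spikes


def competitive_distribution(potentials: np.ndarray) -> np.ndarray:
    """Softmax over potentials, abstracting lateral-inhibition competition.

    Shift-invariant (implemented with max subtraction), so adding a common
    inhibition term to every unit leaves the firing distribution unchanged.
    """
    u = np.asarray(potentials, dtype=float)
    if u.size == 0:
        raise ValueError("empty potential vector")
    if np.isnan(u).any():
        raise ValueError("NaN potential")
    z = np.exp(u - u.max())
    return z / z.sum()


def sample_spike(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw exactly one spike from a categorical distribution."""
    p = np.asarray(probs, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    winner = rng.choice(p.size, p=p / p.sum())
    s = np.zeros(p.size)
    s[winner] = 1.0
    return s


def refractory_term(age: np.ndarray | int, r0: float, tau_r: float) -> np.ndarray | float:
    """Potential subtraction r0*exp(-age/tau_r); zero for never-fired units."""
    age = np.asarray(age)
    r = r0 * np.exp(-age / tau_r)
    return np.where(age == NEVER, 0.0, r)


def step_layer(
    state: LayerState,
    params: LayerParams,
    weight_rows: np.ndarray,
    incoming_spikes: np.ndarray,
    rng: np.random.Generator,
    clamp: np.ndarray | None = None,
) -> LayerState:
    """Advance the layer one step; mutates and returns ``state``.

    Potentials are the summed drive minus each unit's refractory term plus
    Gaussian noise; the softmax of the potentials is stored as
    ``state.distribution`` (the arbitration component reads it) and one
    spike is sampled from it, unless ``clamp`` imposes the spike pattern.
    """
    return step_from_drive(
        state, params, total_activation(weight_rows, incoming_spikes), rng, clamp
    )


def step_from_drive(
    state: LayerState,
    params: LayerParams,
    drive: np.ndarray,
    rng: np.random.Generator,
    clamp: np.ndarray | None = None,
) -> LayerState:
    """As :func:`step_layer`, with the summed synaptic drive precomputed.

    The competition potential is (drive + noise - refractory) / temperature:
    the temperature sets how decisive a given synaptic gap is in the
    winner-take-all competition (temperature 1 recovers the plain softmax
    of the potentials).
    """
    u = drive - params.refractory_gain * refractory_term(
        state.last_spike_age, params.r0, params.tau_r
    )
    if params.noise_sd > 0:
        u = u + rng.normal(0.0, params.noise_sd, size=u.shape)
    u = u / params.temperature
    state.potentials = u
    state.distribution = competitive_distribution(u)
    if clamp is None:
        state.spike = sample_spike(state.distribution, rng)
    else:
        clamp = np.asarray(clamp, dtype=float)
        if clamp.shape != state.spike.shape or not np.isin(clamp, (0.0, 1.0)).all():
            raise ValueError("clamp must be a binary vector of the layer size")
        if clamp.sum() > 1:
            raise ValueError("clamp must activate at most one unit")
        state.spike = clamp.copy()

    fired = state.spike > 0
    aged = state.last_spike_age
    aged[(aged != NEVER)] += 1
    aged[fired] = 0
    return state
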