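"""Entropy-based arbitration between planning and exploration.

The world model's per-cycle uncertainty is the mean, over the cycle's
steps, of the Shannon entropy of the associative layer's firing
distribution, normalized by its maximum ln(K). The arbitration component
compares this uncertainty against a threshold that starts each trial at
epsilon and drops by delta for every failed planning cycle, and selects one
of three modes: keep planning (replan), execute the planned action, or
hand control to the exploration component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventCode, feedback_for_goal

MODES = ("replan", "act_planned", "explore")


@dataclass(frozen=True)
class ArbitrationParams:
    epsilon: float      # threshold at the start of the trial, in (0, 1]
    delta: float        # per-failure decrement, > 0
    max_cycles: int = 50  # hard safety cap on planning cycles per trial

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass(frozen=True)
class ArbitrationDecision:
    mode: str          # one of MODES
    entropy: float     # normalized uncertainty of the deciding cycle
    threshold: float   # threshold value at decision time


def normalized_entropy(distributions: np.ndarray) -> float:
    """Mean per-step entropy over a cycle, scaled to [0, 1] by ln(K).

    ``distributions`` is a (T, K) array of probability vectors; the
    convention 0*ln(0) = 0 applies.
    """
    p = np.asarray(distributions, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if p.shape[1] < 2:
        raise ValueError("need at least two units per distribution")
    sums = p.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-6 or (p < 0).any():
        raise ValueError("rows must be probability vectors summing to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1) / np.log(p.shape[1])
    return float(h.mean())


def threshold(f: int, params: ArbitrationParams) -> float:
    """Entropy threshold after f failed planning cycles: epsilon - f*delta.

    May go negative, which forces exploration since entropy is >= 0.
    """
    if f < 0:
        raise ValueError("failed-cycle count must be >= 0")
    return params.epsilon - f * params.delta


def arbitrate(
    H: float,
    f: int,
    outcome: EventCode | None,
    goal: int,
    params: ArbitrationParams,
) -> ArbitrationDecision:
    """Select the functioning mode after one planning cycle.

    Explore when the uncertainty H reaches the current threshold (or the
    cycle cap); otherwise act on the plan when the cycle's predicted
    outcome matches the goal; otherwise replan (the caller then applies the
    m = -1 goal update and increments f). Callers signal "no executable
    action was read out" by passing outcome=None, which can never match
    the goal. Equality H == threshold counts as too uncertain.
    """
    if not 0 <= H <= 1:
        raise ValueError("normalized entropy must lie in [0, 1]")
    th = threshold(f, params)
    if H >= th or f >= params.max_cycles:
        mode = "explore"
    elif outcome is not None and outcome == feedback_for_goal(goal):
        mode = "act_planned"
    else:
        mode = "replan"
    return ArbitrationDecision(mode=mode, entropy=H, threshold=th)
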