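"""Reference behavioural curves for the fitting harness.

The fitting harness correlates model behaviour against externally supplied
curves. This module reads and writes those curves as plain tabular text
and can generate a SYNTHETIC reference from an ideal-agent-with-lapses
model plus an inverted-U reaction-time template. The synthetic curves are
for exercising the harness only — they are NOT human data and carry no
empirical content.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiment import STIMULI, CurveSet, representative_steps

# staircase: number of forced errors before each stimulus's correct action
# is established (S1 at its 2nd response, S2 at its 4th, S3 at its 5th)
FORCED_ERRORS = {"S1": 1, "S2": 3, "S3": 4}


def synthetic_reference(
    rng: np.random.Generator,
    n_agents: int = 14,
    lapse: float = 0.1,
    n_triplets: int = 20,
    rt_base: float = 1.0,
    rt_peak_height: float = 3.0,
    rt_peak_step: float = 4.0,
    rt_peak_width: float = 2.0,
    rt_noise_sd: float = 0.15,
) -> CurveSet:
    """SYNTHETIC curves from an ideal agent with lapses (not human data).

    Performance: each simulated agent makes the staircase's forced errors,
    then repeats the established action except for occasional lapses.
    Reaction times: a Gaussian bump over the representative steps (slow in
    the middle of learning, fast before and after) plus observation noise.
    """
    perf: dict[str, np.ndarray] = {}
    for label in STIMULI:
        errors = FORCED_ERRORS[label]
        hits = np.zeros((n_agents, n_triplets))
        hits[:, errors:] = rng.random((n_agents, n_triplets - errors)) >= lapse
        perf[label] = hits.mean(axis=0)

    steps = np.array(sorted(set(representative_steps("S1", n_triplets))
                            | set(representative_steps("S2", n_triplets))
                            | set(representative_steps("S3", n_triplets))))
    bump = rt_peak_height * np.exp(-((steps - rt_peak_step) ** 2) / (2 * rt_peak_width**2))
    rt = rt_base + bump + rng.normal(0.0, rt_noise_sd, size=steps.size)
    rt = np.clip(rt, 0.0, None)
    return CurveSet(performance=perf, rt=pd.Series(rt, index=steps, name="rt"))


def save_reference(curves: CurveSet, path) -> None:
    """Write a CurveSet as one tidy CSV (kind, label, x, value)."""
    rows = []
    for label, curve in curves.performance.items():
        for triplet, value in enumerate(curve, start=1):
            rows.append(("performance", label, triplet, value))
    for step, value in curves.rt.items():
        rows.append(("rt", "", int(step), value))
    pd.DataFrame(rows, columns=["kind", "label", "x", "value"]).to_csv(path, index=False)


def load_reference(path) -> CurveSet:
    """Read a CurveSet from the tidy CSV format written by save_reference."""
    table = pd.read_csv(path)
    perf = {}
    for label, grp in table[table["kind"] == "performance"].groupby("label"):
        perf[str(label)] = grp.sort_values("x")["value"].to_numpy()
    rt_rows = table[table["kind"] == "rt"].sort_values("x")
    rt = pd.Series(rt_rows["value"].to_numpy(), index=rt_rows["x"].astype(int).to_numpy())
    return CurveSet(performance=perf, rt=rt)
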