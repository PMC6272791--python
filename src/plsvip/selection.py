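"""Iterative VIP-based descriptor selection.

Each round fits a PLS model on the current descriptor set (component count
re-chosen by LOO q²), records the model's statistics, and keeps only the
descriptors with VIP strictly above 1.  The loop runs until the set stops
shrinking (or becomes degenerate), deliberately past the q² optimum; the
final subset is then chosen from the whole trace — by default the smallest
descriptor count that is a local q² maximum, preferring parsimony over the
global maximum.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import (
    compute_vip,
    fit_pls_nipals,
    loo_q2_per_component,
    predict,
    r_squared,
    rmse,
)

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "vip_iteration_step",
    "run_vip_selection",
    "find_q2_peaks",
    "choose_final_subset",
    "trace_to_frame",
    "trace_from_records",
]

VIP_THRESHOLD = 1.000


class SelectionTerminated(Exception):
    """Raised when no descriptor exceeds the VIP threshold."""


@dataclass
class SelectionStep:
    m: int
    A: int
    r2: float
    rmse: float
    q2: float
    rmsv: float
    retained_names: list[str] = field(default_factory=list)


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_m: int | None = None
    rule_used: str | None = None

    @property
    def final_step(self) -> SelectionStep:
        for s in self.steps:
            if s.m == self.final_m:
                return s
        raise ValueError("final_m does not match any step")


def _fit_current(X: pd.DataFrame, y, A_max: int | None):
    n, m = X.shape
    A_cap = min(10 if A_max is None else A_max, m, n - 2)
    q2s = loo_q2_per_component(X, y, A_cap)
    A = int(np.argmax(q2s)) + 1
    fit = fit_pls_nipals(X, y, A)
    yv = np.asarray(y, dtype=float).ravel()
    press = (1.0 - q2s[A - 1]) * float(np.sum((yv - yv.mean()) ** 2))
    step = SelectionStep(
        m=m,
        A=A,
        r2=r_squared(yv, predict(fit, X)),
        rmse=rmse(yv, predict(fit, X)),
        q2=float(q2s[A - 1]),
        rmsv=float(np.sqrt(press / n)),
    )
    return fit, step


def vip_iteration_step(
    X: pd.DataFrame, y, A_max: int | None = None, vip_weight: str = "y_contribution"
) -> tuple[list[str], SelectionStep]:
    """One selection round on the current descriptor table.

    Fits the model (A chosen by LOO q²), records its statistics, and returns
    the names with VIP > 1 together with the step record of the *current*
    model (i.e. before reduction).  Raises :class:`SelectionTerminated` when
    no descriptor exceeds the threshold (possible only when all VIPs are
    exactly 1, since their mean square is pinned at 1).
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 descriptors to iterate")
    fit, step = _fit_current(X, y, A_max)
    vip = compute_vip(fit, weight=vip_weight)
    retained = [n for n, v in zip(vip.names, vip.vip) if v > VIP_THRESHOLD]
    step.retained_names = list(X.columns)
    if not retained:
        raise SelectionTerminated("no descriptor has VIP > 1")
    return retained, step


def run_vip_selection(
    X: pd.DataFrame,
    y,
    A_max: int | None = None,
    vip_weight: str = "y_contribution",
    max_iter: int = 50,
    rule: str = "smallest_peak",
) -> SelectionTrace:
    """Run the VIP loop to natural termination and choose the final subset.

    Stops when the descriptor count no longer decreases, fewer than 2
    descriptors remain, no VIP exceeds 1, or ``max_iter`` rounds have run.
    ``final_m`` is then set by :func:`choose_final_subset` on the full trace.
    """
    steps: list[SelectionStep] = []
    current = X
    for _ in range(max_iter):
        if current.shape[1] < 2:
            break
        try:
            retained, step = vip_iteration_step(current, y, A_max, vip_weight)
        except SelectionTerminated:
            _, step = _fit_current(current, y, A_max)
            step.retained_names = list(current.columns)
            steps.append(step)
            break
        steps.append(step)
        if len(retained) >= current.shape[1]:
            break
        current = current.loc[:, retained]
    if not steps:  # m == 1 from the start: record the trivial single-column model
        _, step = _fit_current(X, y, A_max)
        step.retained_names = list(X.columns)
        steps.append(step)
    trace = SelectionTrace(steps=steps)
    trace.final_m = choose_final_subset(trace, rule=rule)
    trace.rule_used = rule
    return trace


def find_q2_peaks(trace: SelectionTrace) -> list[int]:
    """Descriptor counts m whose q² is a local maximum along the trace.

    Interior points must strictly exceed both neighbours.  The first step
    counts as a peak when q²[0] >= q²[1] (the loop starts from the full
    model, so a flat or falling start is a peak); the last step only when it
    strictly exceeds its neighbour.  A one-step trace returns its only m.
    """
    q2 = [s.q2 for s in trace.steps]
    ms = [s.m for s in trace.steps]
    if not q2:
        raise ValueError("empty trace")
    if len(q2) == 1:
        return [ms[0]]
    peaks = []
    for i in range(len(q2)):
        if i == 0:
            ok = q2[0] >= q2[1]
        elif i == len(q2) - 1:
            ok = q2[i] > q2[i - 1]
        else:
            ok = q2[i] > q2[i - 1] and q2[i] > q2[i + 1]
        if ok:
            peaks.append(ms[i])
    return peaks


def choose_final_subset(trace: SelectionTrace, rule: str = "smallest_peak") -> int:
    """Pick the final descriptor count from a trace.

    ``smallest_peak`` (default): the smallest m among local q² maxima —
    fewest variables among the near-optimal models.  ``global_max_q2``: the
    m of the single highest q².
    """
    if rule == "smallest_peak":
        peaks = find_q2_peaks(trace)
        if peaks:
            return min(peaks)
        return trace.steps[int(np.argmax([s.q2 for s in trace.steps]))].m
    if rule == "global_max_q2":
        return trace.steps[int(np.argmax([s.q2 for s in trace.steps]))].m
    raise ValueError(f"unknown rule {rule!r}")


def trace_to_frame(trace: SelectionTrace) -> pd.DataFrame:
    """Trace as a table with columns (m, A, r2, RMSE, q2, RMSV)."""
    return pd.DataFrame(
        [
            {"m": s.m, "A": s.A, "r2": s.r2, "RMSE": s.rmse, "q2": s.q2, "RMSV": s.rmsv}
            for s in trace.steps
        ]
    )


def trace_from_records(records) -> SelectionTrace:
    """Build a trace from (m, A, r2, RMSE, q2, RMSV) records (e.g. a published table)."""
    steps = [
        SelectionStep(m=int(r[0]), A=int(r[1]), r2=float(r[2]), rmse=float(r[3]),
                      q2=float(r[4]), rmsv=float(r[5]))
        for r in records
    ]
    if any(b.m >= a.m for a, b in zip(steps, steps[1:])):
        raise ValueError("descriptor counts must strictly decrease along a trace")
    return SelectionTrace(steps=steps)
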