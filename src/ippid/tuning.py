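"""Closed-loop step-response evaluation and PID tuning.

The average PID gains are judged on the closed-loop response of the average
glucose–insulin transfer function to a reference step, simulated in deviation
coordinates with the *pure linear* PID (no output clamping, integral always
active): the tuning target is a linear object, and the two summary numbers —
the 10%-to-90% rise time and the percent overshoot — trade promptness against
hypoglycemia risk.  With the design gains on the average plant the loop
settles with a rise time of about 130 min and an overshoot of about 2.2%.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .controller import PIDParameters
from .tf import TransferFunctionModel


@dataclass(frozen=True)
class StepResponseSummary:
    rise_time: float      # min, 10% -> 90% of the final value
    overshoot: float      # percent of the final value
    final_value: float
    settled: bool


def simulate_closed_loop_step(plant: TransferFunctionModel,
                              params: PIDParameters,
                              T: float = 5.0,
                              duration: float = 2000.0,
                              step_size: float = 1.0) -> np.ndarray:
    """Controlled-output trace for a reference step at t = 0.

    Deviation coordinates, zero initial state.  At each control step the
    output is computed from past inputs through the plant difference
    equation, the tracking error (step minus output) feeds the linear PID
    with the integral accumulating T*E(k) unconditionally, and the insulin
    command is applied without clamping.
    """
    if not plant.is_stable:
        raise ValueError("plant must be stable")
    a1, a2, a3 = plant.a
    b = plant.gain
    d = plant.delay_steps
    n = int(round(duration / T))
    y = np.zeros(n)
    u = np.zeros(n)
    integral = 0.0
    prev_error = 0.0
    for k in range(n):
        y[k] = (-a1 * (y[k - 1] if k >= 1 else 0.0)
                - a2 * (y[k - 2] if k >= 2 else 0.0)
                - a3 * (y[k - 3] if k >= 3 else 0.0)
                + b * (u[k - d] if k >= d else 0.0))
        error = step_size - y[k]
        integral += T * error
        u[k] = (params.kp * error
                + params.kd * (error - prev_error) / T
                + params.ki * integral)
        prev_error = error
    return y


def is_settled(trace: np.ndarray, rel_band: float = 0.005,
               tail_frac: float = 0.1) -> bool:
    """Last ``tail_frac`` of the trace within ``rel_band`` of the final value."""
    final = trace[-1]
    if not np.all(np.isfinite(trace)) or final == 0.0:
        return False
    tail = trace[-max(int(tail_frac * trace.size), 2):]
    return bool(np.max(np.abs(tail - final)) <= rel_band * abs(final))


def rise_time(trace: np.ndarray, T: float) -> float:
    """10%-to-90% rise time with linear interpolation between samples."""
    final = trace[-1]
    if final == 0.0:
        raise ValueError("not settled: zero final value")

    def first_crossing(level: float) -> float:
        above = trace >= level if final > 0 else trace <= level
        idx = int(np.argmax(above))
        if not above[idx]:
            raise ValueError(f"not settled: trace never reaches {level:g}")
        if idx == 0:
            return 0.0
        frac = (level - trace[idx - 1]) / (trace[idx] - trace[idx - 1])
        return (idx - 1 + frac) * T

    return first_crossing(0.9 * final) - first_crossing(0.1 * final)


def overshoot(trace: np.ndarray) -> float:
    """Peak excess above the final value, percent of the final value."""
    final = trace[-1]
    if final == 0.0:
        raise ValueError("overshoot undefined for zero final value")
    peak = np.max(trace) if final > 0 else np.min(trace)
    return max(0.0, (peak - final) / final * 100.0)


def summarize_step(trace: np.ndarray, T: float) -> StepResponseSummary:
    settled = is_settled(trace)
    if not settled:
        return StepResponseSummary(rise_time=np.nan, overshoot=np.nan,
                                   final_value=float(trace[-1]) if np.all(np.isfinite(trace)) else np.nan,
                                   settled=False)
    return StepResponseSummary(rise_time=rise_time(trace, T),
                               overshoot=overshoot(trace),
                               final_value=float(trace[-1]), settled=True)


def evaluate_pid(plant: TransferFunctionModel, params: PIDParameters,
                 T: float = 5.0, duration: float = 2000.0) -> StepResponseSummary:
    """Step-response summary of one candidate gain set."""
    trace = simulate_closed_loop_step(plant, params, T=T, duration=duration)
    return summarize_step(trace, T)


def default_grid(center: PIDParameters, n: int = 5,
                 span: float = 2.0):
    """Logarithmic grid of gain candidates around a center point."""
    factors = np.logspace(-np.log10(span), np.log10(span), n)
    grid = []
    for fp, fi, fd in itertools.product(factors, repeat=3):
        grid.append(PIDParameters(center.kp * fp, center.ki * fi,
                                  center.kd * fd))
    return grid


def tune_pid(plant: TransferFunctionModel, grid=None,
             max_overshoot: float = 5.0, T: float = 5.0,
             duration: float = 2000.0):
    """Pick the grid point with the smallest rise time subject to an
    overshoot constraint.

    Ties break toward smaller overshoot, then smaller |Kd|.  If no candidate
    settles under the constraint, the settled candidate with the smallest
    overshoot is returned with a warning.
    Returns (PIDParameters, StepResponseSummary).
    """
    from .controller import AVERAGE_PID
    grid = list(grid) if grid is not None else default_grid(AVERAGE_PID)
    if not grid:
        raise ValueError("empty candidate grid")
    evaluated = [(p, evaluate_pid(plant, p, T=T, duration=duration))
                 for p in grid]
    settled = [(p, s) for p, s in evaluated if s.settled]
    if not settled:
        raise ValueError("no candidate produced a settled response")
    feasible = [(p, s) for p, s in settled if s.overshoot <= max_overshoot]
    if feasible:
        return min(feasible,
                   key=lambda ps: (ps[1].rise_time, ps[1].overshoot,
                                   abs(ps[0].kd)))
    warnings.warn("no candidate meets the overshoot constraint "
                  f"{max_overshoot:g}%; returning the best-overshoot one")
    return min(settled, key=lambda ps: (ps[1].overshoot, ps[1].rise_time))
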