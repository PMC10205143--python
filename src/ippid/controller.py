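"""Discrete PID insulin controller with conditional anti-windup and
personalization.

The control law on the 5-min grid, with tracking error E(k) = R - Gm_hat(k)
(reference R = 110 mg/dl, the middle of the tight euglycemic range), is

    I(k) = Kp E(k) + Kd (E(k) - E(k-1))/T + Ki * S(k),

where the running integral S obeys the conditional (anti-windup) update

    S(k) = S(k-1) + T E(k)   if Gm_hat(k) <= 140 mg/dl,
    S(k) = S(k-1)            otherwise.

Above 140 mg/dl the patient is most likely in a prandial phase: the error is
driven by the meal, which the integral action cannot compensate, so the
integral — whose job is to converge to the basal-equivalent rate — is frozen.
The output is clamped to [0, max_rate]; the previous error always updates so
the derivative stays well defined.

Personalization divides all three average gains by a patient coefficient K':

* CR mode (time-varying): K'(h) = CRF(h)/CR_max, where CRF is the patient's
  piecewise-constant carbohydrate-ratio day curve smoothed by an acausal
  low-pass (cutoff 1/300 min^-1) to avoid parameter discontinuities.
* TDI mode (constant): K' = TDI_max/TDI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import (CR_MAX_DEFAULT, TDI_MAX_DEFAULT, PatientProfile,
                         segment_profile)
from .smoothing import smooth_periodic

REFERENCE_DEFAULT = 110.0       # mg/dl
INTEGRAL_GATE = 140.0           # mg/dl, upper bound of the tight range
CONTROL_PERIOD = 5.0            # min
MAX_RATE_DEFAULT = 15.0         # U/h
CR_CUTOFF = 1.0 / 300.0         # 1/min


@dataclass(frozen=True)
class PIDParameters:
    """PID gains for the negative-gain glucose–insulin plant (all <= 0)."""

    kp: float  # (U/h)/(mg/dl)
    ki: float  # (U/h)/(mg/dl*min)
    kd: float  # (U/h)*min/(mg/dl)

    def __post_init__(self):
        if not all(np.isfinite(v) for v in (self.kp, self.ki, self.kd)):
            raise ValueError("gains must be finite")
        if self.kp > 0 or self.ki > 0 or self.kd > 0:
            raise ValueError("gains must be <= 0 for a negative-gain plant")

    def scaled(self, factor: float) -> "PIDParameters":
        return PIDParameters(self.kp * factor, self.ki * factor, self.kd * factor)


#: Average PID gains from the step-response tuning on the average TF.
AVERAGE_PID = PIDParameters(kp=-0.0665, ki=-1.9342e-4, kd=-2.0922)


@dataclass
class ControllerState:
    prev_error: float = 0.0     # mg/dl
    integral: float = 0.0       # mg/dl*min
    last_output: float = 0.0    # U/h
    time_of_day: float = 0.0    # min


def smooth_cr_profile(cr_b: float, cr_l: float, cr_d: float,
                      cutoff: float = CR_CUTOFF, dt: float = 1.0) -> np.ndarray:
    """Smoothed 24-h carbohydrate-ratio curve CRF(h), g/U.

    Acausal (zero-phase) low-pass of the piecewise-constant B/L/D signal;
    periodic over the day, mean-preserving, and bounded by the input range.
    Returned on a grid of ``dt``-minute samples.
    """
    if min(cr_b, cr_l, cr_d) <= 0:
        raise ValueError("carbohydrate ratios must be positive")
    coarse = segment_profile((cr_b, cr_l, cr_d), dt=dt)
    return smooth_periodic(coarse, dt=dt, cutoff=cutoff)


@dataclass(frozen=True)
class PersonalizationSchedule:
    """Time profile of the personalization coefficient K'."""

    mode: str                      # "CR" | "TDI" | "none"
    crf: np.ndarray | None = None  # smoothed CR curve on a 1-min grid, g/U
    cr_max: float = CR_MAX_DEFAULT
    tdi: float | None = None
    tdi_max: float = TDI_MAX_DEFAULT

    def __post_init__(self):
        if self.mode not in ("CR", "TDI", "none"):
            raise ValueError("mode must be 'CR', 'TDI' or 'none'")
        if self.mode == "CR":
            if self.crf is None or np.min(self.crf) <= 0:
                raise ValueError("CR mode needs a positive crf curve")
        if self.mode == "TDI" and not (self.tdi and self.tdi > 0):
            raise ValueError("TDI mode needs a positive tdi")


def personalization_gain(schedule: PersonalizationSchedule, h: float) -> float:
    """K' at time-of-day ``h`` (minutes)."""
    if schedule.mode == "CR":
        crf = schedule.crf
        idx = int((h % 1440.0) / 1440.0 * crf.size) % crf.size
        return float(crf[idx] / schedule.cr_max)
    if schedule.mode == "TDI":
        return float(schedule.tdi_max / schedule.tdi)
    return 1.0


def personalize(avg: PIDParameters, k_prime: float) -> PIDParameters:
    """Divide every average gain by K' (larger K' -> gentler controller)."""
    if k_prime <= 0:
        raise ValueError("K' must be positive")
    return avg.scaled(1.0 / k_prime)


def pid_step(state: ControllerState, g_meas: float,
             params: PIDParameters,
             reference: float = REFERENCE_DEFAULT,
             T: float = CONTROL_PERIOD,
             max_rate: float = MAX_RATE_DEFAULT,
             integral_gate: float = INTEGRAL_GATE):
    """One controller update; returns (insulin rate U/h, new state).

    A non-finite measurement holds the previous output and leaves the state
    untouched apart from the clock.
    """
    if T <= 0:
        raise ValueError("control period must be positive")
    if not np.isfinite(g_meas):
        new = replace_state(state, time_of_day=(state.time_of_day + T) % 1440.0)
        return state.last_output, new
    error = reference - g_meas
    integral = state.integral
    if g_meas <= integral_gate:
        integral = integral + T * error
    raw = (params.kp * error
           + params.kd * (error - state.prev_error) / T
           + params.ki * integral)
    rate = float(np.clip(raw, 0.0, max_rate))
    new = ControllerState(prev_error=error, integral=integral,
                          last_output=rate,
                          time_of_day=(state.time_of_day + T) % 1440.0)
    return rate, new


def replace_state(state: ControllerState, **kw) -> ControllerState:
    return ControllerState(
        prev_error=kw.get("prev_error", state.prev_error),
        integral=kw.get("integral", state.integral),
        last_output=kw.get("last_output", state.last_output),
        time_of_day=kw.get("time_of_day", state.time_of_day))


class PIDController:
    """Stepping PID with a (possibly time-varying) personalization schedule."""

    def __init__(self, schedule: PersonalizationSchedule,
                 avg_params: PIDParameters = AVERAGE_PID,
                 reference: float = REFERENCE_DEFAULT,
                 T: float = CONTROL_PERIOD,
                 max_rate: float = MAX_RATE_DEFAULT,
                 integral_gate: float = INTEGRAL_GATE,
                 start_time_of_day: float = 0.0):
        self.schedule = schedule
        self.avg_params = avg_params
        self.reference = reference
        self.T = T
        self.max_rate = max_rate
        self.integral_gate = integral_gate
        self.state = ControllerState(time_of_day=start_time_of_day % 1440.0)

    def gains_at(self, h: float) -> PIDParameters:
        return personalize(self.avg_params,
                           personalization_gain(self.schedule, h))

    def step(self, g_meas: float, time_of_day: float | None = None) -> float:
        """One 5-min update; ``time_of_day`` (min) overrides the internal clock."""
        if time_of_day is not None:
            self.state.time_of_day = time_of_day % 1440.0
        params = self.gains_at(self.state.time_of_day)
        rate, self.state = pid_step(
            self.state, g_meas, params, reference=self.reference, T=self.T,
            max_rate=self.max_rate, integral_gate=self.integral_gate)
        return rate


def make_controller(mode: str, profile: PatientProfile,
                    avg_params: PIDParameters = AVERAGE_PID,
                    cr_max: float = CR_MAX_DEFAULT,
                    tdi_max: float = TDI_MAX_DEFAULT,
                    **kwargs) -> PIDController:
    """Controller personalized from a patient's clinical parameters."""
    if mode == "CR":
        crf = smooth_cr_profile(profile.cr_b, profile.cr_l, profile.cr_d)
        schedule = PersonalizationSchedule(mode="CR", crf=crf, cr_max=cr_max)
    elif mode == "TDI":
        if not profile.tdi or profile.tdi <= 0:
            raise ValueError("TDI personalization needs a positive tdi")
        schedule = PersonalizationSchedule(mode="TDI", tdi=profile.tdi,
                                           tdi_max=tdi_max)
    elif mode == "none":
        schedule = PersonalizationSchedule(mode="none")
    else:
        raise ValueError("mode must be 'CR', 'TDI' or 'none'")
    return PIDController(schedule, avg_params=avg_params, **kwargs)
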