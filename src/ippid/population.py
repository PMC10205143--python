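"""Synthetic virtual-patient cohort and glucose–insulin plant.

The cohort is a self-contained stand-in for a full metabolic simulator: each
virtual patient is driven by an individual third-order glucose–insulin
transfer function whose poles and gain scatter around the population-average
values, plus additive endogenous production (with a dawn-phenomenon morning
rise), meal-driven glucose appearance, and a circadian insulin-sensitivity
multiplier on the insulin input.

Clinical parameters are generated consistently with the dynamics: the three
carbohydrate-to-insulin ratios (CR, g/U) are anchored to the patient's TF-gain
ratio (more insulin-sensitive patients have both a larger |gain| and a higher
CR), and the total daily insulin (TDI, U) is derived from the basal rate and
the mean daily meal load through the CRs.  This keeps both personalization
schemes (CR-based and TDI-based) meaningful on the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import smooth_periodic
from .tf import (AVERAGE_COMPLEX_POLE, AVERAGE_GAIN, AVERAGE_REAL_POLE,
                 TransferFunctionModel)

# Day segmentation for meal-indexed quantities (CR, insulin sensitivity):
# breakfast [05:00-11:00), lunch [11:00-17:00), dinner [17:00-05:00).
SEGMENT_EDGES_MIN = (300, 660, 1020)

#: Population maxima used to normalize the personalization gains.
CR_MAX_DEFAULT = 39.8381   # g/U
TDI_MAX_DEFAULT = 97.9932  # U

MEAN_MEAL_GRAMS = (40.0, 80.0, 60.0)  # breakfast, lunch, dinner CHO, g


@dataclass(frozen=True)
class PopulationConfig:
    """Distributions of the synthetic cohort.

    ``dispersion`` scales every inter-patient spread at once; 0 collapses the
    cohort onto the population-average patient.
    """

    dispersion: float = 1.0
    real_pole_sd: float = 0.004
    complex_re_sd: float = 0.03
    complex_im_sd: float = 0.03
    gain_log_sd: float = 0.3          # lognormal spread of the gain ratio
    cr_log_sd: float = 0.05           # idiosyncratic CR scatter beyond the gain link
    cr_max: float = CR_MAX_DEFAULT
    cr_min: float = 3.0
    tdi_max: float = TDI_MAX_DEFAULT
    si_mid: tuple = (0.75, 0.925, 0.85)   # circadian sensitivity midpoints B/L/D
    si_half_width: tuple = (0.20, 0.175, 0.20)
    equilibrium_mean: float = 300.0   # zero-insulin steady-state glucose, mg/dl
    equilibrium_sd: float = 25.0
    basal_target: float = 115.0       # fasting glucose the basal rate aims at, mg/dl
    meal_gain_mean: float = 0.8       # peak mg/dl rise per g CHO
    meal_gain_sd: float = 0.12
    meal_tau: float = 40.0            # absorption time constant, min
    dawn_amplitude_mid: float = 0.10
    dawn_amplitude_half_width: float = 0.04
    dawn_window_min: tuple = (240, 480)   # 04:00-08:00
    si_noise_sd: float = 0.2          # daily Gaussian(1, 0.2) meal-time perturbation
    si_floor: float = 0.05
    si_cutoff: float = 1.0 / 300.0    # smoothing cutoff of the daily path, 1/min
    robust_shift_range: tuple = (0.7, 1.3)
    max_redraws: int = 100


@dataclass(frozen=True)
class PatientProfile:
    """One synthetic patient."""

    id: int
    tf: TransferFunctionModel
    cr_b: float
    cr_l: float
    cr_d: float
    tdi: float
    basal_rate: float        # U/h
    egp_offset: float        # constant endogenous term c_e of the ARX output eq, mg/dl
    meal_gain: float         # peak mg/dl per g CHO
    dawn_amplitude: float    # fractional EGP increase
    si_nominal: tuple        # (breakfast, lunch, dinner) sensitivity multipliers

    def __post_init__(self):
        for name in ("cr_b", "cr_l", "cr_d"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be positive")
        if not (self.tdi > 0):
            raise ValueError("tdi must be positive")
        if not self.tf.is_stable:
            raise ValueError("patient TF must be stable")
        if not (self.tf.gain < 0):
            raise ValueError("patient TF gain must be negative")
        if not all(s > 0 for s in self.si_nominal):
            raise ValueError("si_nominal must be positive")

    @property
    def crs(self) -> tuple:
        return (self.cr_b, self.cr_l, self.cr_d)

    @property
    def equilibrium_glucose(self) -> float:
        """Zero-insulin open-loop steady-state glucose, mg/dl."""
        denom = float(np.prod([1.0 - p for p in self.tf.poles]).real)
        return self.egp_offset / denom


@dataclass(frozen=True)
class SensitivityPath:
    """Dense insulin-sensitivity multiplier over one day."""

    day_index: int
    values: np.ndarray  # one sample per ``dt`` minutes over 24 h
    setup: str          # "standard" | "robust"
    dt: float = 0.5


def _draw_pair(rng, cfg: PopulationConfig):
    """Draw a stable conjugate pole pair around the population average."""
    d = cfg.dispersion
    for _ in range(cfg.max_redraws):
        re = rng.normal(AVERAGE_COMPLEX_POLE.real, cfg.complex_re_sd * d)
        im = abs(rng.normal(AVERAGE_COMPLEX_POLE.imag, cfg.complex_im_sd * d))
        im = max(im, 0.01)
        if 0.0 < re and np.hypot(re, im) < 0.995:
            return complex(re, im)
    raise RuntimeError("failed to draw a stable complex pole pair "
                       f"after {cfg.max_redraws} attempts")


def make_population(n: int, seed: int, config: PopulationConfig | None = None):
    """Generate ``n`` patient profiles, deterministic in ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 911]))
    d = cfg.dispersion
    profiles = []
    for i in range(n):
        for _ in range(cfg.max_redraws):
            p_real = rng.normal(AVERAGE_REAL_POLE, cfg.real_pole_sd * d)
            if 0.9 < p_real < 0.9985:
                break
        else:
            raise RuntimeError("failed to draw a stable real pole")
        p_c = _draw_pair(rng, cfg)
        kappa = float(np.exp(rng.normal(-0.5 * (cfg.gain_log_sd * d) ** 2,
                                        cfg.gain_log_sd * d)))
        gain = AVERAGE_GAIN * kappa
        tf = TransferFunctionModel(gain=gain,
                                   poles=(p_real, p_c, np.conj(p_c)))

        si = tuple(mid + hw * d * rng.uniform(-1.0, 1.0)
                   for mid, hw in zip(cfg.si_mid, cfg.si_half_width))

        crs = []
        for f in si:
            cr = cfg.cr_max * kappa * f * np.exp(rng.normal(0.0, cfg.cr_log_sd * d))
            crs.append(float(np.clip(cr, cfg.cr_min, cfg.cr_max)))

        g0 = float(np.clip(rng.normal(cfg.equilibrium_mean, cfg.equilibrium_sd * d),
                           200.0, 400.0))
        dcg = tf.dc_gain()  # negative
        basal = (g0 - cfg.basal_target) / (-dcg * si[2])
        egp_offset = g0 * float(np.prod([1.0 - p for p in tf.poles]).real)
        tdi = 24.0 * basal + sum(g / cr for g, cr in zip(MEAN_MEAL_GRAMS, crs))
        tdi = min(tdi, cfg.tdi_max)
        meal_gain = float(np.clip(rng.normal(cfg.meal_gain_mean, cfg.meal_gain_sd * d),
                                  0.4, 1.6))
        dawn = cfg.dawn_amplitude_mid + cfg.dawn_amplitude_half_width * d * rng.uniform(-1, 1)
        profiles.append(PatientProfile(
            id=i, tf=tf, cr_b=crs[0], cr_l=crs[1], cr_d=crs[2], tdi=tdi,
            basal_rate=basal, egp_offset=egp_offset, meal_gain=meal_gain,
            dawn_amplitude=dawn, si_nominal=si))
    return profiles


def segment_profile(values_bld, dt: float = 1.0) -> np.ndarray:
    """Piecewise-constant daily curve from (breakfast, lunch, dinner) values.

    Segments: breakfast [05:00-11:00), lunch [11:00-17:00), dinner
    [17:00-05:00) wrapping past midnight.  Sampled every ``dt`` minutes.
    """
    b, l, dn = values_bld
    n = int(round(1440 / dt))
    t = np.arange(n) * dt
    out = np.full(n, dn, dtype=float)
    out[(t >= SEGMENT_EDGES_MIN[0]) & (t < SEGMENT_EDGES_MIN[1])] = b
    out[(t >= SEGMENT_EDGES_MIN[1]) & (t < SEGMENT_EDGES_MIN[2])] = l
    return out


def robust_shift(profile: PatientProfile, seed: int,
                 config: PopulationConfig | None = None) -> float:
    """Per-patient systematic sensitivity shift of the robust setup.

    One multiplicative factor drawn uniformly from [0.7, 1.3], constant over
    the whole experiment: it models a systematic error in the nominal
    clinical parameters, not day-to-day variability.
    """
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), profile.id, 7001]))
    lo, hi = cfg.robust_shift_range
    return float(rng.uniform(lo, hi))


def sensitivity_path(profile: PatientProfile, day: int, setup: str = "standard",
                     seed: int = 0, dt: float = 0.5,
                     config: PopulationConfig | None = None) -> SensitivityPath:
    """Daily insulin-sensitivity multiplier path.

    The nominal path connects the patient's breakfast/lunch/dinner
    sensitivities smoothly (periodic Gaussian smoothing).  Each day the three
    meal-time values are perturbed multiplicatively by Gaussian(1, 0.2) draws
    before smoothing; the robust setup additionally applies the patient's
    systematic shift factor.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    if setup not in ("standard", "robust"):
        raise ValueError("setup must be 'standard' or 'robust'")
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), profile.id, day, 7002]))
    draws = 1.0 + cfg.si_noise_sd * rng.standard_normal(3)
    vals = [max(s * g, cfg.si_floor) for s, g in zip(profile.si_nominal, draws)]
    coarse = segment_profile(vals, dt=1.0)
    smooth = smooth_periodic(coarse, dt=1.0, cutoff=cfg.si_cutoff)
    if dt != 1.0:
        n = int(round(1440 / dt))
        t = np.arange(n) * dt
        ext_t = np.arange(1441.0)
        ext_v = np.concatenate([smooth, smooth[:1]])
        smooth = np.interp(t, ext_t, ext_v)
    if setup == "robust":
        smooth = smooth * robust_shift(profile, seed, cfg)
    smooth = np.maximum(smooth, cfg.si_floor)
    return SensitivityPath(day_index=day, values=smooth, setup=setup, dt=dt)


def dawn_bump(t_min_of_day: np.ndarray, window=(240, 480)) -> np.ndarray:
    """Unit-peak dawn-phenomenon window: sin^2 bump over 04:00-08:00."""
    t = np.asarray(t_min_of_day, dtype=float) % 1440.0
    lo, hi = window
    out = np.zeros_like(t)
    inside = (t >= lo) & (t < hi)
    out[inside] = np.sin(np.pi * (t[inside] - lo) / (hi - lo)) ** 2
    return out


def meal_response(grams: float, profile: PatientProfile, dt: float = 0.5,
                  duration: float = 600.0, tau: float = 40.0) -> np.ndarray:
    """Glucose-appearance time course of a meal, mg/dl on the plant output.

    Two-compartment linear absorption with equal time constants
    (impulse response proportional to t·exp(-t/tau)); the peak equals
    ``meal_gain * grams`` mg/dl at t = tau, and the whole curve scales
    linearly with the carbohydrate amount.
    """
    if grams < 0:
        raise ValueError("grams must be nonnegative")
    t = np.arange(int(round(duration / dt))) * dt
    shape = (t / tau) * np.exp(1.0 - t / tau)
    return profile.meal_gain * grams * shape


@dataclass
class PlantState:
    """Internal state of the linear plant realization."""

    modes: np.ndarray          # complex modal states, shape (3,)
    delay_buffer: np.ndarray   # effective insulin input, oldest first
    G: float                   # current blood glucose, mg/dl


class Plant:
    """Modal realization of a patient's TF at a fine internal step.

    The 5-min poles are mapped to the internal step ``dt`` as p**(dt/5) and
    the per-mode input coefficients are scaled so that, with insulin held
    constant over each 5-min control period, the plant sampled every 5 min
    reproduces the patient's ARX difference equation exactly.
    """

    def __init__(self, profile: PatientProfile, dt: float = 0.5):
        self.profile = profile
        self.dt = dt
        tfm = profile.tf
        ratio = dt / tfm.period
        n_sub = tfm.period / dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("dt must divide the control period")
        poles = np.asarray(tfm.poles, dtype=complex)
        # residues of 1/prod(1 - p_i z^-1) = sum r_i / (1 - p_i z^-1)
        self.residues = np.array([
            1.0 / np.prod([1.0 - poles[j] / poles[i]
                           for j in range(3) if j != i])
            for i in range(3)])
        self.sub_poles = poles ** ratio
        self.sub_b = (1.0 - self.sub_poles) / (1.0 - poles)
        self.out_c = tfm.gain * self.residues
        # One step of the TF delay is inherent in the zero-order-hold
        # discretization (input over [k, k+1) first appears in the state at
        # k+1), so the explicit buffer holds delay_steps - 1 control periods.
        if tfm.delay_steps < 1:
            raise ValueError("delay_steps must be >= 1")
        self.delay_sub = int(round((tfm.delay_steps - 1) * tfm.period / dt))

    def steady_state(self, insulin_rate: float, si: float = 1.0,
                     egp: float | None = None) -> PlantState:
        """State at open-loop equilibrium under a constant effective input."""
        w = si * insulin_rate
        egp = self.profile.equilibrium_glucose if egp is None else egp
        modes = np.full(3, w, dtype=complex) / (1.0 - np.asarray(self.profile.tf.poles))
        buf = np.full(self.delay_sub, w)
        g = egp + float(np.real(self.out_c @ modes))
        return PlantState(modes=modes, delay_buffer=buf, G=max(g, 0.0))


def plant_step(state: PlantState, plant: Plant, insulin_rate: float, si: float,
               ra_meal: float, egp: float, dt: float | None = None):
    """Advance the plant one internal step; returns (new_state, G).

    ``egp`` is the current endogenous output term in mg/dl (equilibrium
    glucose, already including any dawn-phenomenon multiplier); ``ra_meal``
    the current meal appearance, mg/dl.
    """
    if insulin_rate < 0:
        raise ValueError("insulin_rate must be nonnegative")
    if dt is not None and abs(dt - plant.dt) > 1e-12:
        raise ValueError("dt does not match the plant realization step")
    w_now = si * insulin_rate
    if state.delay_buffer.size:
        w_delayed = state.delay_buffer[0]
        buf = np.empty_like(state.delay_buffer)
        buf[:-1] = state.delay_buffer[1:]
        buf[-1] = w_now
    else:
        w_delayed = w_now
        buf = state.delay_buffer
    modes = plant.sub_poles * state.modes + plant.sub_b * w_delayed
    g = egp + float(np.real(plant.out_c @ modes)) + ra_meal
    if not np.isfinite(g):
        raise FloatingPointError("non-finite glucose in plant step")
    g = max(g, 0.0)
    return PlantState(modes=modes, delay_buffer=buf, G=g), g


# ---------------------------------------------------------------------------
# CSV round-trip of a population

def population_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        real, pair = p.tf.classify_poles()
        rows.append(dict(
            id=p.id, pole_real=real, pole_c_re=pair.real, pole_c_im=pair.imag,
            gain=p.tf.gain, cr_b=p.cr_b, cr_l=p.cr_l, cr_d=p.cr_d, tdi=p.tdi,
            basal_rate=p.basal_rate, egp_offset=p.egp_offset,
            meal_gain=p.meal_gain, dawn_amplitude=p.dawn_amplitude,
            si_b=p.si_nominal[0], si_l=p.si_nominal[1], si_d=p.si_nominal[2]))
    return pd.DataFrame(rows)


def population_from_frame(df: pd.DataFrame):
    profiles = []
    for _, r in df.iterrows():
        pc = complex(r.pole_c_re, r.pole_c_im)
        tfm = TransferFunctionModel(gain=r.gain,
                                    poles=(r.pole_real, pc, np.conj(pc)))
        profiles.append(PatientProfile(
            id=int(r.id), tf=tfm, cr_b=r.cr_b, cr_l=r.cr_l, cr_d=r.cr_d,
            tdi=r.tdi, basal_rate=r.basal_rate, egp_offset=r.egp_offset,
            meal_gain=r.meal_gain, dawn_amplitude=r.dawn_amplitude,
            si_nominal=(r.si_b, r.si_l, r.si_d)))
    return profiles
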