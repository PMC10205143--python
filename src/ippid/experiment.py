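"""End-to-end closed-loop experiments.

``run_closed_loop`` advances one patient through a meal scenario on a 30-s
internal grid (plant + sensing) with a 5-min control period; the controller
sees only filtered glucose measurements and the clock — never the meal
events.  ``run_experiment`` runs the CR-personalized and TDI-personalized
arms on bit-identical disturbance realizations (same scenarios, sensitivity
paths and sensor noise; paired design) and tabulates the glycemic metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .controller import PIDController, make_controller
from .metrics import build_report, glycemic_metrics, postprandial_mask
from .population import (Plant, PatientProfile, PopulationConfig, dawn_bump,
                         make_population, meal_response, sensitivity_path)
from .protocol import (HypoTreatmentConfig, MealEvent, Scenario,
                       generate_scenario)
from .sensing import SensorConfig


def _child_seed(root: int, *tags: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(root), *[int(t) for t in tags]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class ClosedLoopResult:
    """Per-patient simulation record on the 5-min report grid."""

    t: np.ndarray          # absolute min from scenario start
    G: np.ndarray          # true glucose at report times, mg/dl
    Gm_hat: np.ndarray     # filtered measurement, mg/dl
    insulin: np.ndarray    # commanded rate over the following 5 min, U/h
    rescues: list          # MealEvent list
    integral: np.ndarray   # controller integral at each step, mg/dl*min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "G": self.G, "Gm_hat": self.Gm_hat,
                             "I": self.insulin, "integral": self.integral})


def run_closed_loop(profile: PatientProfile, controller: PIDController,
                    scenario: Scenario,
                    sensor: SensorConfig | None = None,
                    setup: str | None = None,
                    sensitivity_seed: int = 0, noise_seed: int = 0,
                    dt: float = 0.5,
                    ht_config: HypoTreatmentConfig | None = None,
                    population_config: PopulationConfig | None = None,
                    variability: bool = True) -> ClosedLoopResult:
    """Simulate one patient over the scenario in closed loop.

    ``variability=False`` freezes the sensitivity path at 1 and disables the
    dawn phenomenon (used for regulation checks).  The rescue policy acts on
    the same filtered measurement the controller receives.
    """
    sensor = sensor or SensorConfig()
    ht = ht_config or HypoTreatmentConfig()
    setup = setup or scenario.setup
    pcfg = population_config or PopulationConfig()
    n_days = scenario.days
    steps_day = int(round(1440.0 / dt))
    n = n_days * steps_day
    sub_per_ctrl = int(round(controller.T / dt))

    # --- precomputed disturbance boards -----------------------------------
    if variability:
        si = np.concatenate([
            sensitivity_path(profile, day, setup, sensitivity_seed, dt=dt,
                             config=pcfg).values
            for day in range(n_days)])
        bump = dawn_bump(np.arange(steps_day) * dt, pcfg.dawn_window_min)
        egp = profile.equilibrium_glucose * (
            1.0 + profile.dawn_amplitude * np.tile(bump, n_days))
    else:
        si = np.ones(n)
        egp = np.full(n, profile.equilibrium_glucose)

    ra = np.zeros(n + 1)
    curve_cache: dict[float, np.ndarray] = {}

    def add_meal(grams: float, start_idx: int):
        if grams <= 0:
            return
        key = round(grams, 6)
        if key not in curve_cache:
            curve_cache[key] = meal_response(grams, profile, dt=dt)
        c = curve_cache[key]
        stop = min(start_idx + c.size, ra.size)
        if stop > start_idx:
            ra[start_idx:stop] += c[:stop - start_idx]

    for e in scenario.events:
        add_meal(e.grams, int(round(e.t_abs / dt)))

    rng = np.random.default_rng(noise_seed)
    noise = rng.standard_normal(n) if sensor.noise_cv > 0 else np.zeros(n)

    # --- plant and sensor scalar constants --------------------------------
    plant = Plant(profile, dt=dt)
    q1, q2, q3 = (complex(v) for v in plant.sub_poles)
    b1, b2, b3 = (complex(v) for v in plant.sub_b)
    c1, c2, c3 = (complex(v) for v in plant.out_c)
    state0 = plant.steady_state(profile.basal_rate, si=float(si[0]),
                                egp=float(egp[0]))
    x1, x2, x3 = (complex(v) for v in state0.modes)
    dbuf = list(state0.delay_buffer)
    dlen = len(dbuf)
    dpos = 0

    decay = math.exp(-dt / sensor.tau)
    gain_lag = 1.0 - decay
    theta_steps = sensor.theta / dt
    noise_cv = sensor.noise_cv

    G = np.empty(n + 1)
    G[0] = state0.G
    gm = state0.G
    win = [state0.G] * sensor.window
    wpos = 0
    wsum = state0.G * sensor.window

    n_reports = n // sub_per_ctrl
    t_rep = np.empty(n_reports)
    G_rep = np.empty(n_reports)
    ghat_rep = np.empty(n_reports)
    i_rep = np.empty(n_reports)
    integ_rep = np.empty(n_reports)
    rescues: list[MealEvent] = []
    last_rescue = -math.inf

    rate = profile.basal_rate
    rep = 0
    for j in range(n):
        # plant substep (insulin held since the last control update)
        if dlen:
            w = dbuf[dpos]
            dbuf[dpos] = si[j] * rate
            dpos = (dpos + 1) % dlen
        else:
            w = si[j] * rate
        x1 = q1 * x1 + b1 * w
        x2 = q2 * x2 + b2 * w
        x3 = q3 * x3 + b3 * w
        g = egp[j] + (c1 * x1 + c2 * x2 + c3 * x3).real + ra[j + 1]
        if not math.isfinite(g):
            raise FloatingPointError(
                f"non-finite glucose at substep {j} (patient {profile.id})")
        g = max(g, 0.0)
        G[j + 1] = g

        # sensor lag: exact discretization, delayed G linearly interpolated
        pos = j - theta_steps  # index of G(t_j - theta) in G[..] grid offset by 1
        if pos <= 0:
            g_del = G[0]
        else:
            lo = math.floor(pos)
            frac = pos - lo
            g_del = G[lo] * (1.0 - frac) + G[lo + 1] * frac
        gm = decay * gm + gain_lag * g_del
        g_noisy = gm + noise[j] * noise_cv * g
        if g_noisy < 0.0:
            g_noisy = 0.0

        # onboard moving average over the last `window` 30-s samples
        wsum += g_noisy - win[wpos]
        win[wpos] = g_noisy
        wpos = (wpos + 1) % sensor.window

        if (j + 1) % sub_per_ctrl == 0:
            t_now = (j + 1) * dt
            g_hat = wsum / sensor.window
            new_rate = controller.step(g_hat, time_of_day=t_now % 1440.0)
            if g_hat < ht.threshold and t_now - last_rescue >= ht.lockout:
                add_meal(ht.grams, j + 1)
                last_rescue = t_now
                day, tod = divmod(t_now, 1440.0)
                rescues.append(MealEvent(day=int(day), time=tod,
                                         grams=ht.grams, kind="rescue"))
            t_rep[rep] = t_now
            G_rep[rep] = g
            ghat_rep[rep] = g_hat
            i_rep[rep] = new_rate
            integ_rep[rep] = controller.state.integral
            rate = new_rate
            rep += 1

    return ClosedLoopResult(t=t_rep, G=G_rep, Gm_hat=ghat_rep, insulin=i_rep,
                            rescues=rescues, integral=integ_rep)


@dataclass(frozen=True)
class ExperimentConfig:
    """Specification of a two-arm paired experiment."""

    n_patients: int = 100
    weeks: int = 12
    setup: str = "standard"            # "standard" | "robust"
    seed: int = 0
    arms: tuple = ("TDI", "CR")
    warmup_days: int = 1               # excluded from metrics
    dt: float = 0.5                    # internal step, min
    pp_horizon: float = 240.0          # post-prandial window, min
    sensor: SensorConfig = field(default_factory=SensorConfig)
    ht: HypoTreatmentConfig = field(default_factory=HypoTreatmentConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (("sensor", SensorConfig), ("ht", HypoTreatmentConfig),
                         ("population", PopulationConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "arms" in d:
            d["arms"] = tuple(d["arms"])
        return cls(**d)


def run_patient_arms(profile: PatientProfile, scenario: Scenario,
                     config: ExperimentConfig):
    """Run every arm of one patient on identical disturbances."""
    sens_seed = _child_seed(config.seed, 1, profile.id)
    noise_seed = _child_seed(config.seed, 2, profile.id)
    out = {}
    for arm in config.arms:
        controller = make_controller(arm, profile)
        out[arm] = run_closed_loop(
            profile, controller, scenario, sensor=config.sensor,
            setup=config.setup, sensitivity_seed=sens_seed,
            noise_seed=noise_seed, dt=config.dt, ht_config=config.ht,
            population_config=config.population)
    return out


def run_experiment(config: ExperimentConfig, outdir: str | None = None,
                   population=None):
    """Full paired experiment; returns (MetricsReport, ht_counts, population).

    Metrics are computed on true glucose at the 5-min report grid, excluding
    the warm-up day(s), for the whole record (D&N) and the union of 4-h
    post-prandial windows (PP).
    """
    if population is None:
        population = make_population(config.n_patients,
                                     _child_seed(config.seed, 0),
                                     config.population)
    rows = {arm: [] for arm in config.arms}
    ht_counts = {arm: [] for arm in config.arms}
    warm = config.warmup_days * 1440.0
    for profile in population:
        scenario = generate_scenario(config.weeks,
                                     seed=_child_seed(config.seed, 3, profile.id),
                                     setup=config.setup)
        results = run_patient_arms(profile, scenario, config)
        for arm, res in results.items():
            keep = res.t >= warm
            pp = postprandial_mask(scenario, res.t, config.pp_horizon) & keep
            for window, mask in (("D&N", keep), ("PP", pp)):
                vals = glycemic_metrics(res.G, mask)
                vals.update(patient=profile.id, window=window)
                rows[arm].append(vals)
            ht_counts[arm].append(
                sum(1 for e in res.rescues if e.t_abs >= warm))
    arm_frames = {arm: pd.DataFrame(r) for arm, r in rows.items()}
    report = build_report(arm_frames, ht_counts)
    if outdir is not None:
        path = Path(outdir)
        path.mkdir(parents=True, exist_ok=True)
        report.table.to_csv(path / "report.csv", index=False)
        report.per_patient.to_csv(path / "per_patient_metrics.csv", index=False)
        (path / "config.json").write_text(json.dumps(
            {"n_patients": config.n_patients, "weeks": config.weeks,
             "setup": config.setup, "seed": config.seed,
             "arms": list(config.arms)}, indent=2))
    return report, ht_counts, population
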