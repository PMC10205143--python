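"""Randomized meal protocol and hypo-treatment rescue policy.

The evaluation protocol runs for 12 weeks with three daily meals at uniform
random times and carbohydrate amounts (breakfast 07:00-08:30, 40 g +/- 20%;
lunch 12:30-13:30, 80 g +/- 20%; dinner 19:30-20:30, 60 g +/- 20%), plus up
to two snacks (20 g +/- 20%), each present with probability 50% about two
hours after breakfast or lunch.

Rescue carbohydrates: the trigger rule is a clinical-convention stand-in
(15 g when the filtered measurement drops below 65 mg/dl, 30-min lockout);
all three numbers are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

MAIN_MEALS = ("breakfast", "lunch", "dinner")

MEAL_TIME_RANGES = {  # min of day
    "breakfast": (420.0, 510.0),
    "lunch": (750.0, 810.0),
    "dinner": (1170.0, 1230.0),
}
MEAL_GRAM_RANGES = {
    "breakfast": (32.0, 48.0),
    "lunch": (64.0, 96.0),
    "dinner": (48.0, 72.0),
}
SNACK_GRAM_RANGE = (16.0, 24.0)
SNACK_PROBABILITY = 0.5
SNACK_DELAY = 120.0       # min after the parent meal
SNACK_JITTER = 15.0       # +/- min, uniform


@dataclass(frozen=True)
class MealEvent:
    day: int
    time: float     # min of day, [0, 1440)
    grams: float
    kind: str       # breakfast|lunch|dinner|snack|rescue

    def __post_init__(self):
        if self.grams < 0:
            raise ValueError("grams must be nonnegative")
        if not (0 <= self.time < 1440):
            raise ValueError("time must be in [0, 1440)")

    @property
    def t_abs(self) -> float:
        """Absolute time from the start of the scenario, min."""
        return self.day * 1440.0 + self.time


@dataclass(frozen=True)
class Scenario:
    weeks: int
    events: tuple
    setup: str = "standard"
    seed: int = 0

    @property
    def days(self) -> int:
        return self.weeks * 7

    def main_meals(self):
        return [e for e in self.events if e.kind in MAIN_MEALS]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dict(day=e.day, time=e.time, grams=e.grams,
                                  kind=e.kind) for e in self.events])

    def header(self) -> str:
        return json.dumps(dict(weeks=self.weeks, setup=self.setup,
                               seed=self.seed))


def generate_scenario(weeks: int = 12, seed: int = 0,
                      setup: str = "standard") -> Scenario:
    """Randomized meal/snack scenario, deterministic in ``seed``."""
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3001]))
    events = []
    for day in range(weeks * 7):
        meal_times = {}
        for kind in MAIN_MEALS:
            t = rng.uniform(*MEAL_TIME_RANGES[kind])
            g = rng.uniform(*MEAL_GRAM_RANGES[kind])
            meal_times[kind] = t
            events.append(MealEvent(day=day, time=t, grams=g, kind=kind))
        for parent in ("breakfast", "lunch"):
            present = rng.uniform() < SNACK_PROBABILITY
            t = meal_times[parent] + SNACK_DELAY + rng.uniform(-SNACK_JITTER,
                                                               SNACK_JITTER)
            g = rng.uniform(*SNACK_GRAM_RANGE)
            if present:
                events.append(MealEvent(day=day, time=t % 1440.0, grams=g,
                                        kind="snack"))
    events.sort(key=lambda e: e.t_abs)
    return Scenario(weeks=weeks, events=tuple(events), setup=setup, seed=seed)


@dataclass(frozen=True)
class HypoTreatmentConfig:
    threshold: float = 65.0   # mg/dl, on the filtered measurement
    grams: float = 15.0
    lockout: float = 30.0     # min


def hypo_treatment_policy(t: np.ndarray, g_meas: np.ndarray,
                          config: HypoTreatmentConfig | None = None):
    """Rescue events triggered by a measurement trace on the report grid.

    Returns (list of trigger times, number of treatments).  A rescue is
    dispensed when the measurement drops below the threshold and no rescue
    was given within the lockout window.
    """
    cfg = config or HypoTreatmentConfig()
    times = []
    last = -np.inf
    for ti, gi in zip(np.asarray(t, float), np.asarray(g_meas, float)):
        if gi < cfg.threshold and ti - last >= cfg.lockout:
            times.append(float(ti))
            last = ti
    return times, len(times)


def ht_percent(counts) -> float:
    """Percentage of patients with at least one hypo treatment."""
    counts = list(counts)
    if not counts:
        raise ValueError("empty cohort")
    return 100.0 * sum(1 for c in counts if c >= 1) / len(counts)
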