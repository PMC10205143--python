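"""Intraperitoneal glucose-sensing chain.

The sensor model is a first-order lag with delay,

    dGm/dt = (G(t - theta) - Gm(t)) / tau,

with multiplicative Gaussian measurement noise (sd = 5% of the current blood
glucose) added to 30-s samples, and an onboard moving-average filter that
averages the last ten samples; the controller receives the filtered value
every 5 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SensorConfig:
    tau: float = 5.6            # lag time constant, min
    theta: float = 0.68         # pure delay, min
    noise_cv: float = 0.05      # noise sd as a fraction of current glucose
    sample_period: float = 30.0  # s
    window: int = 10            # moving-average length, samples
    report_period: float = 5.0  # min
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        if not (0 <= self.noise_cv < 1):
            raise ValueError("noise_cv must be in [0, 1)")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        ratio = self.report_period * 60.0 / self.sample_period
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("report_period must be a multiple of sample_period")

    @property
    def sample_dt_min(self) -> float:
        return self.sample_period / 60.0

    @property
    def samples_per_report(self) -> int:
        return int(round(self.report_period * 60.0 / self.sample_period))


@dataclass
class GlucoseTraces:
    """Aligned traces through the sensing chain."""

    t: np.ndarray         # min, sample grid
    G: np.ndarray         # true blood glucose
    Gm: np.ndarray        # lagged sensor glucose
    Gm_noisy: np.ndarray  # noise-corrupted samples
    t_report: np.ndarray  # min, report grid
    Gm_hat: np.ndarray    # filtered values delivered to the controller

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t, "G": self.G, "Gm": self.Gm,
                           "Gm_noisy": self.Gm_noisy})
        rep = pd.DataFrame({"t": self.t_report, "Gm_hat": self.Gm_hat})
        return df.merge(rep, on="t", how="left")


def sensor_lag(t: np.ndarray, G: np.ndarray, config: SensorConfig) -> np.ndarray:
    """First-order lag with delay, exact discretization on the given grid.

    Gm(t+dt) = e^(-dt/tau) Gm(t) + (1 - e^(-dt/tau)) G(t - theta), with the
    delayed glucose linearly interpolated (held at G(0) before the record
    starts).  Gm(0) is initialized to G(0).
    """
    t = np.asarray(t, dtype=float)
    G = np.asarray(G, dtype=float)
    if t.size != G.size or t.size < 2:
        raise ValueError("t and G must be equal-length traces of >= 2 samples")
    span = t[-1] - t[0]
    if span <= config.theta:
        raise ValueError(
            f"trace spans {span:.2f} min, shorter than the sensor delay "
            f"theta={config.theta} min")
    dt = t[1] - t[0]
    decay = np.exp(-dt / config.tau)
    delayed = np.interp(t - config.theta, t, G, left=G[0])
    Gm = np.empty_like(G)
    Gm[0] = G[0]
    for k in range(1, t.size):
        Gm[k] = decay * Gm[k - 1] + (1.0 - decay) * delayed[k - 1]
    return Gm


def add_noise(Gm: np.ndarray, config: SensorConfig, seed: int | None = None,
              G_true: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative Gaussian measurement noise, floored at zero.

    The noise sd is ``noise_cv`` times the current *blood* glucose when
    ``G_true`` is given, otherwise times the lagged sensor glucose.
    """
    Gm = np.asarray(Gm, dtype=float)
    basis = Gm if G_true is None else np.asarray(G_true, dtype=float)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    noisy = Gm + rng.standard_normal(Gm.size) * (config.noise_cv * basis)
    return np.maximum(noisy, 0.0)


def onboard_filter(Gm_noisy: np.ndarray, config: SensorConfig,
                   t0: float = 0.0):
    """Moving-average filter and 5-min reporting.

    Each report is the arithmetic mean of the last ``window`` 30-s samples;
    during start-up (fewer samples than the window) the available samples are
    averaged.  Reports are emitted every ``report_period`` minutes, the first
    one ``report_period`` after ``t0``.
    Returns (t_report [min], Gm_hat).
    """
    x = np.asarray(Gm_noisy, dtype=float)
    m = config.samples_per_report
    w = config.window
    idx = np.arange(m - 1, x.size, m)  # sample index at each report time
    csum = np.concatenate([[0.0], np.cumsum(x)])
    starts = np.maximum(idx + 1 - w, 0)
    means = (csum[idx + 1] - csum[starts]) / (idx + 1 - starts)
    t_report = t0 + (idx + 1) * config.sample_dt_min
    return t_report, means


def sense(t: np.ndarray, G: np.ndarray, config: SensorConfig,
          seed: int | None = None) -> GlucoseTraces:
    """Full chain: lag -> noise -> onboard filter."""
    Gm = sensor_lag(t, G, config)
    Gm_noisy = add_noise(Gm, config, seed=seed, G_true=G)
    t_report, Gm_hat = onboard_filter(Gm_noisy, config, t0=float(t[0]))
    return GlucoseTraces(t=t, G=G, Gm=Gm, Gm_noisy=Gm_noisy,
                         t_report=t_report, Gm_hat=Gm_hat)
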