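"""ARX identification of the glucose–insulin transfer function.

A 24-h meal-free excitation protocol drives each virtual patient with
low-pass-filtered Gaussian insulin noise (cutoff 1/30 min^-1, negative values
saturated at zero) while the measurement noise is switched off.  The 5-min
input/output records are fitted by ordinary least squares to the third-order
ARX model

    Gm(k) + a1 Gm(k-1) + a2 Gm(k-2) + a3 Gm(k-3) = b I(k-3) + e(k) + c_e,

whose pole polynomial and input coefficient give the patient's transfer
function.  Population poles and gains are then averaged (poles and gains, not
polynomial coefficients) to obtain the control-relevant average TF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .population import Plant, PatientProfile, plant_step
from .sensing import SensorConfig, onboard_filter, sensor_lag
from .tf import TransferFunctionModel, poles_from_arx

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ARXFit:
    """OLS estimate of the third-order ARX model."""

    a1: float
    a2: float
    a3: float
    b: float
    ce: float
    residual_var: float
    n_samples: int

    def __post_init__(self):
        vals = (self.a1, self.a2, self.a3, self.b, self.ce)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("ARX coefficients must be finite")
        if self.n_samples < 5:
            raise ValueError("need at least 5 samples (number of unknowns)")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.b, self.ce])


def generate_excitation(duration: float = 1440.0, cutoff: float = 1.0 / 30.0,
                        amplitude_sd: float = 1.0, seed: int = 0,
                        period: float = 5.0, order: int = 4) -> np.ndarray:
    """Excitation insulin trace on the control grid, U/h.

    Zero-mean Gaussian noise of sd ``amplitude_sd`` filtered forward with a
    Butterworth low-pass at ``cutoff`` (1/min); negative values saturated to
    zero.
    """
    if amplitude_sd < 0:
        raise ValueError("amplitude_sd must be nonnegative")
    n = int(round(duration / period))
    rng = np.random.default_rng(seed)
    white = amplitude_sd * rng.standard_normal(n)
    if amplitude_sd == 0:
        return np.zeros(n)
    nyq = 0.5 / period
    ba = signal.butter(order, cutoff / nyq, btype="low")
    filtered = signal.lfilter(*ba, white)
    return np.maximum(filtered, 0.0)


def fit_arx(insulin: np.ndarray, glucose: np.ndarray) -> ARXFit:
    """Ordinary least squares on the ARX normal equations.

    The regressor row at step k is [-Gm(k-1), -Gm(k-2), -Gm(k-3), I(k-3), 1];
    the solve uses a numerically stable least-squares routine, equivalent to
    (X'X)^-1 X'Y for full-rank X.
    """
    I = np.asarray(insulin, dtype=float)
    Gm = np.asarray(glucose, dtype=float)
    if I.size != Gm.size:
        raise ValueError("insulin and glucose traces must be aligned")
    n = Gm.size
    if n < 8:
        raise ValueError("need at least 8 samples")
    Y = Gm[3:]
    X = np.column_stack([-Gm[2:-1], -Gm[1:-2], -Gm[:-3], I[:-3],
                         np.ones(n - 3)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "singular regressor matrix (rank "
            f"{rank} < {X.shape[1]}): input/output not exciting enough")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = max(Y.size - X.shape[1], 1)
    return ARXFit(a1=coef[0], a2=coef[1], a3=coef[2], b=coef[3], ce=coef[4],
                  residual_var=float(resid @ resid / dof), n_samples=Y.size)


def arx_to_tf(fit: ARXFit, period: float = 5.0) -> TransferFunctionModel:
    """Transfer function of an ARX fit: poles from the lag polynomial, K = b."""
    poles = poles_from_arx(fit.a1, fit.a2, fit.a3)
    tfm = TransferFunctionModel(gain=fit.b, poles=tuple(poles),
                                delay_steps=3, period=period)
    if not tfm.is_stable:
        raise ValueError("identified TF has an unstable pole "
                         f"(max |p| = {max(abs(p) for p in tfm.poles):.4f})")
    return tfm


def average_population_tf(tfs) -> TransferFunctionModel:
    """Average TF: mean real pole, mean conjugate pair, mean gain.

    TFs that do not decompose into one real pole plus a conjugate pair
    (e.g. three real poles) are excluded and counted in the log.
    """
    tfs = list(tfs)
    reals, pairs, gains = [], [], []
    excluded = 0
    for tfm in tfs:
        try:
            r, c = tfm.classify_poles()
        except ValueError:
            excluded += 1
            continue
        reals.append(r)
        pairs.append(c)
        gains.append(tfm.gain)
    if not reals:
        raise ValueError("no TF with a real pole plus conjugate pair")
    if excluded:
        log.warning("average_population_tf: excluded %d of %d TFs "
                    "(no real+conjugate-pair structure)", excluded, len(tfs))
    pair = complex(np.mean([c.real for c in pairs]),
                   np.mean([abs(c.imag) for c in pairs]))
    period = tfs[0].period
    return TransferFunctionModel(gain=float(np.mean(gains)),
                                 poles=(float(np.mean(reals)), pair, np.conj(pair)),
                                 period=period)


def identification_dataset(profile: PatientProfile, seed: int = 0,
                           duration: float = 1440.0,
                           amplitude_sd: float = 1.0,
                           sensor: SensorConfig | None = None,
                           dt: float = 0.5):
    """Simulate the meal-free excitation protocol for one patient.

    The plant is driven open loop (sensitivity 1, dawn off, no meals) by the
    excitation added on top of the basal rate; glucose passes through the
    sensing chain with the measurement noise set to zero.  Returns a frame
    with columns (t, I, Gm_hat) on the 5-min grid.
    """
    sensor = sensor or SensorConfig(noise_cv=0.0)
    period = profile.tf.period
    excitation = generate_excitation(duration, amplitude_sd=amplitude_sd,
                                     seed=seed, period=period)
    insulin = profile.basal_rate + excitation
    plant = Plant(profile, dt=dt)
    state = plant.steady_state(profile.basal_rate)
    sub_per_ctrl = int(round(period / dt))
    n_sub = excitation.size * sub_per_ctrl
    G = np.empty(n_sub + 1)
    G[0] = state.G
    for j in range(n_sub):
        rate = insulin[j // sub_per_ctrl]
        state, g = plant_step(state, plant, rate, 1.0, 0.0,
                              profile.equilibrium_glucose)
        G[j + 1] = g
    t = np.arange(n_sub + 1) * dt
    Gm = sensor_lag(t, G, sensor)
    t_rep, Gm_hat = onboard_filter(Gm[1:], sensor, t0=0.0)
    # Step k of the ARX grid: measurement at t = 5k (the t=0 value is the
    # steady state), input I(k) applied over [5k, 5(k+1)).
    n = insulin.size
    Gm_grid = np.concatenate([[G[0]], Gm_hat])[:n]
    t_grid = np.arange(n) * period
    return pd.DataFrame({"t": t_grid, "I": insulin, "Gm_hat": Gm_grid})


def run_identification_protocol(population, seed: int = 0,
                                duration: float = 1440.0,
                                amplitude_sd: float = 1.0,
                                sensor: SensorConfig | None = None):
    """Per-patient excitation, ARX fit and population-average TF.

    Returns (fits, tfs, average_tf, summary frame).  Patients whose fit has
    an unstable pole or lacks the real+conjugate-pair structure are excluded
    from the average (counted in the summary).
    """
    fits, tfs, rows = [], [], []
    for p in population:
        data = identification_dataset(p, seed=seed + p.id, duration=duration,
                                      amplitude_sd=amplitude_sd, sensor=sensor)
        fit = fit_arx(data["I"].to_numpy(), data["Gm_hat"].to_numpy())
        fits.append(fit)
        row = dict(id=p.id, a1=fit.a1, a2=fit.a2, a3=fit.a3, b=fit.b,
                   ce=fit.ce, usable=True)
        try:
            tfm = arx_to_tf(fit, period=p.tf.period)
            r, c = tfm.classify_poles()
            row.update(pole_real=r, pole_c_re=c.real, pole_c_im=c.imag,
                       gain=tfm.gain)
            tfs.append(tfm)
        except ValueError:
            row["usable"] = False
        rows.append(row)
    if not tfs:
        raise ValueError("no usable ARX fit in the population")
    avg = average_population_tf(tfs)
    return fits, tfs, avg, pd.DataFrame(rows)
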