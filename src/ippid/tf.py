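"""Discrete glucose–insulin transfer-function model.

The control-relevant model of the insulin-to-glucose channel is a third-order
discrete transfer function with a three-step delay on the 5-min control grid::

    G(z)/I(z) = K z^-3 / ((1 - p1 z^-1)(1 - p2 z^-1)(1 - p3 z^-1))

with one slow real pole (module close to 1) and a faster complex-conjugate
pair.  The gain K is negative: insulin lowers glucose.  Equivalently, in the
time domain the model is the ARX difference equation

    G(k) + a1 G(k-1) + a2 G(k-2) + a3 G(k-3) = b I(k-3) + c_e

with ``[1, a1, a2, a3]`` the expansion of the pole polynomial and ``b = K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Population-average poles and gain of the identified glucose–insulin TF.
AVERAGE_REAL_POLE = 0.9887
AVERAGE_COMPLEX_POLE = 0.8353 + 0.1949j
AVERAGE_GAIN = -0.0769  # (mg/dl)/(U/h)


@dataclass(frozen=True)
class TransferFunctionModel:
    """Third-order discrete TF with delay on the control grid.

    Parameters
    ----------
    gain : float
        Steady-state numerator gain K, (mg/dl)/(U/h).  Negative for a
        physiological insulin–glucose channel.
    poles : tuple of complex
        The three poles; complex poles must occur in conjugate pairs.
    delay_steps : int
        Pure input delay in control periods (3 by default).
    period : float
        Sampling/control period in minutes (5 by default).
    """

    gain: float
    poles: tuple = field(default=(AVERAGE_REAL_POLE,
                                  AVERAGE_COMPLEX_POLE,
                                  np.conj(AVERAGE_COMPLEX_POLE)))
    delay_steps: int = 3
    period: float = 5.0

    def __post_init__(self):
        poles = tuple(complex(p) for p in self.poles)
        object.__setattr__(self, "poles", poles)
        if len(poles) != 3:
            raise ValueError("expected exactly three poles")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")

    @property
    def is_stable(self) -> bool:
        return all(abs(p) < 1.0 for p in self.poles)

    def denominator(self) -> np.ndarray:
        """Monic pole polynomial ``[1, a1, a2, a3]`` in z^-1 powers.

        Real coefficients are returned when the poles form a conjugate set.
        """
        coeffs = np.poly(np.asarray(self.poles, dtype=complex))
        if np.max(np.abs(coeffs.imag)) < 1e-9:
            coeffs = coeffs.real
        return coeffs

    @property
    def a(self) -> tuple:
        """ARX output-lag coefficients (a1, a2, a3)."""
        den = self.denominator()
        return tuple(float(c) for c in den[1:])

    def dc_gain(self) -> float:
        """Steady-state gain K / prod(1 - p_i), (mg/dl)/(U/h)."""
        denom = np.prod([1.0 - p for p in self.poles])
        return float((self.gain / denom).real)

    def classify_poles(self):
        """Split poles into (real_pole, upper_half_plane_complex_pole).

        Raises ``ValueError`` when the poles are not one real value plus a
        conjugate pair (within tolerance), e.g. three real poles.
        """
        poles = np.asarray(self.poles, dtype=complex)
        imag = np.abs(poles.imag)
        order = np.argsort(imag)
        real_candidate, pair = poles[order[0]], poles[order[1:]]
        if imag[order[0]] > 1e-8 * max(1.0, np.max(np.abs(poles))):
            raise ValueError("no real pole found")
        if np.abs(pair[0] - np.conj(pair[1])) > 1e-6 or abs(pair[0].imag) < 1e-8:
            raise ValueError("poles are not a real value plus a conjugate pair")
        upper = pair[np.argmax(pair.imag)]
        return float(real_candidate.real), complex(upper)

    def step_response(self, n_steps: int, amplitude: float = 1.0) -> np.ndarray:
        """Open-loop response to a unit-held input step (deviation coords)."""
        a1, a2, a3 = self.a
        d = self.delay_steps
        y = np.zeros(n_steps)
        for k in range(n_steps):
            u = amplitude if k - d >= 0 else 0.0
            y[k] = (-a1 * (y[k - 1] if k >= 1 else 0.0)
                    - a2 * (y[k - 2] if k >= 2 else 0.0)
                    - a3 * (y[k - 3] if k >= 3 else 0.0)
                    + self.gain * u)
        return y


def average_tf() -> TransferFunctionModel:
    """The population-average transfer function."""
    return TransferFunctionModel(gain=AVERAGE_GAIN)


def poles_from_arx(a1: float, a2: float, a3: float) -> np.ndarray:
    """Roots of z^3 + a1 z^2 + a2 z + a3 (the TF poles)."""
    return np.roots([1.0, a1, a2, a3])
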