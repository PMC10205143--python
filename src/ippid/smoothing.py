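"""Zero-phase periodic smoothing used for daily profiles.

Daily profiles (carbohydrate-ratio curves, insulin-sensitivity paths) are
piecewise-constant over meal segments and must be smoothed acausally so the
result is 24-h periodic, keeps the daily mean, and introduces no values
outside the input range.  A circular Gaussian kernel has all three properties
(it is a convex combination of input samples), unlike a recursive zero-phase
filter which can overshoot at segment edges.  The kernel width is stated as a
low-pass cutoff: the -3 dB point of the kernel's transfer function.
"""

from __future__ import annotations

import numpy as np


def gaussian_sigma_for_cutoff(cutoff: float) -> float:
    """Kernel sigma (min) whose frequency response is -3 dB at ``cutoff`` (1/min).

    The Fourier transform of a Gaussian of width sigma is
    exp(-2 pi^2 f^2 sigma^2); solving for half power at f = cutoff gives
    sigma = sqrt(ln 2 / 2) / (2 pi cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return float(np.sqrt(np.log(2.0) / 2.0) / (2.0 * np.pi * cutoff))


def smooth_periodic(values: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    """Circular Gaussian smoothing of a periodic daily signal.

    Parameters
    ----------
    values : array
        Samples of one period, uniformly spaced ``dt`` minutes apart.
    dt : float
        Sample spacing, min.
    cutoff : float
        Low-pass cutoff, 1/min (e.g. 1/300 for the carbohydrate-ratio curve).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("values must be a 1-D array with at least 2 samples")
    sigma = gaussian_sigma_for_cutoff(cutoff) / dt  # in samples
    n = values.size
    half = min(int(np.ceil(4.0 * sigma)), n // 2)
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    idx = (np.arange(n)[:, None] + offsets[None, :]) % n
    return values[idx] @ kernel
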