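"""Seeded synthetic-signal generators used as entropy benchmarks.

All generators are pure functions of their parameters and a seed: the same
seed always reproduces the same signal.  The families covered are colored
noise (white / pink / brown, i.e. spectral exponents 0 / -1 / -2), the
logistic map (periodic through chaotic regimes as the control parameter
moves from 3.5 to 4), the MIX process (a sinusoid whose samples are
replaced by uniform noise with probability p, sweeping regularity from
periodic to random), additive white Gaussian noise at a prescribed SNR,
and a noisy sinusoid used to probe noise sensitivity of ordinal methods.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "colored_noise",
    "logistic_map",
    "mix_process",
    "add_noise_at_snr",
    "noisy_sinusoid",
]

_SLOPES = {"white": 0.0, "pink": -1.0, "brown": -2.0}


def colored_noise(
    color: str, n: int, seed: int | np.random.Generator | None = None
) -> NDArray[np.float64]:
    """Generate white, pink (1/f) or brown (1/f^2) noise.

    White noise is i.i.d. standard Gaussian.  Pink and brown noise are
    synthesized by shaping the Fourier amplitudes of a white draw by
    ``f**(-1/2)`` and ``f**(-1)`` respectively (random phases inherited
    from the white draw, zero DC), then rescaling to zero mean and unit
    variance.  FFT shaping gives the exact target spectral slope, unlike
    recursive filtering.
    """
    if color not in _SLOPES:
        raise ValueError(f"color must be one of {sorted(_SLOPES)}, got {color!r}")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    if color == "white":
        return white
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (_SLOPES[color] / 2.0)
    x = np.fft.irfft(spectrum * shape, n)
    return (x - x.mean()) / x.std()


def logistic_map(
    alpha: float | ArrayLike,
    n: int,
    x0: float = 0.23,
    burn_in: int = 0,
) -> NDArray[np.float64]:
    """Iterate the logistic map ``x_{j+1} = alpha_j x_j (1 - x_j)``.

    ``alpha`` may be a scalar or a per-sample schedule of length
    ``n + burn_in`` (e.g. a linear ramp from 3.5 to 3.99 for bifurcation
    sweeps).  Initial states on the unstable finite orbits of alpha=4
    (0, 0.25, 0.5, 0.75, 1) are rejected, as are parameters that drive the
    state out of [0, 1].
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if x0 in (0.0, 0.25, 0.5, 0.75, 1.0) or not 0.0 < x0 < 1.0:
        raise ValueError(f"initial state x0={x0} is degenerate for the logistic map")
    total = n + burn_in
    alpha_arr = np.asarray(alpha, dtype=float)
    if alpha_arr.ndim == 0:
        alpha_arr = np.full(total, float(alpha_arr))
    elif alpha_arr.shape[0] != total:
        raise ValueError(
            f"alpha schedule length {alpha_arr.shape[0]} != n + burn_in = {total}"
        )
    x = np.empty(total)
    state = float(x0)
    for j in range(total):
        state = alpha_arr[j] * state * (1.0 - state)
        if not 0.0 <= state <= 1.0:
            raise ValueError(
                f"logistic map diverged at step {j} (alpha={alpha_arr[j]})"
            )
        x[j] = state
    return x[burn_in:]


def mix_process(
    p: float | ArrayLike,
    n: int,
    seed: int | np.random.Generator | None = None,
    *,
    sine_amplitude: float = np.sqrt(2.0),
    noise_bound: float = np.sqrt(3.0),
    period: int = 12,
) -> NDArray[np.float64]:
    """MIX process: ``MIX_k = (1 - z_k) x_k + z_k y_k``.

    ``x_k = A sin(2 pi k / period)`` is the deterministic component,
    ``y_k ~ Uniform(-b, b)`` the stochastic one, and ``z_k ~ Bernoulli(p)``
    selects which appears.  ``p`` may be a per-sample schedule (e.g. a
    linear ramp from 0.99 down to 0.01) so the series evolves from
    randomness to orderliness.  The default amplitude ``sqrt(2)`` and
    bound ``sqrt(3)`` give both components unit variance, the convention
    of the original regularity-statistic literature; pass
    ``sine_amplitude=2, noise_bound=3`` for the literal constants.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    if p_arr.ndim != 0 and p_arr.shape[0] != n:
        raise ValueError(f"p schedule length {p_arr.shape[0]} != n = {n}")
    rng = np.random.default_rng(seed)
    k = np.arange(1, n + 1)
    x = sine_amplitude * np.sin(2.0 * np.pi * k / period)
    y = rng.uniform(-noise_bound, noise_bound, n)
    z = rng.random(n) < p_arr
    return np.where(z, y, x)


def add_noise_at_snr(
    x: ArrayLike, snr_db: float, seed: int | np.random.Generator | None = None
) -> NDArray[np.float64]:
    """Add white Gaussian noise scaled to a target SNR in dB.

    The noise variance is ``var(x) / 10**(snr_db / 10)`` so that
    ``10 log10(var(x) / var(noise)) = snr_db``.
    """
    x = np.asarray(x, dtype=float)
    var = x.var()
    if var == 0.0:
        raise ValueError("signal variance is zero; SNR undefined")
    rng = np.random.default_rng(seed)
    noise_sd = np.sqrt(var / 10.0 ** (snr_db / 10.0))
    return x + noise_sd * rng.standard_normal(x.size)


def noisy_sinusoid(
    n: int = 400, seed: int | np.random.Generator | None = None
) -> NDArray[np.float64]:
    """``x_i = sin(i / 20) + 0.3 U(0, 1)``, i = 1..n.

    A slow sinusoid with small uniform noise: ordinal methods see the
    noise-scrambled local ranks and report near-maximal entropy, while
    amplitude-aware class-based methods stay well below their maximum.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n + 1)
    return np.sin(i / 20.0) + 0.3 * rng.random(n)
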