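"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: Bessel evaluation by
power series and by integral representation (not scipy.special.i0e/i1e),
diffusion by particle-level random walks (not density-field convolution),
and moments by direct per-pixel loops (not the mapper).
"""

from __future__ import annotations

import math

import numpy as np


def bessel_i_series(n: int, x: float, terms: int = 20) -> float:
    """Modified Bessel I_n(x) by its ascending power series (small x)."""
    total = 0.0
    for m in range(terms):
        total += (x / 2.0) ** (2 * m + n) / (math.factorial(m) * math.factorial(m + n))
    return total


def axelrod_series(A: float, tau_d: float, t: float, terms: int = 20) -> float:
    """Recovery model via the 20-term power series for I0 and I1."""
    if t == 0:
        return 0.0
    x = 2.0 * tau_d / t
    return A * math.exp(-x) * (bessel_i_series(0, x, terms) + bessel_i_series(1, x, terms))


def scaled_bessel_i_quadrature(n: int, x, n_theta: int = 8001):
    """exp(-x) I_n(x) via the integral representation.

    e^{-x} I_n(x) = (1/pi) \\int_0^pi e^{x (cos(theta) - 1)} cos(n theta) dtheta.
    The integrand is bounded by 1 for all x >= 0, so this stays
    well-conditioned where the power series overflows; trapezoidal
    quadrature of the smooth periodic integrand converges spectrally.
    """
    theta = np.linspace(0.0, np.pi, n_theta)
    x = np.asarray(x, dtype=float)[..., None]
    integrand = np.exp(x * (np.cos(theta) - 1.0)) * np.cos(n * theta)
    return np.trapezoid(integrand, theta, axis=-1) / np.pi


def axelrod_quadrature(A, tau_d, t):
    """Recovery model via quadrature Bessel evaluation (any argument size)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = 2.0 * tau_d / t[pos]
    out[pos] = A * (scaled_bessel_i_quadrature(0, x) + scaled_bessel_i_quadrature(1, x))
    return out


def particle_frap_recovery(
    *,
    n_particles: int,
    mobile_fraction: float,
    diffusion_coeff: float,
    frame_interval_s: float,
    n_steps: int,
    strip_height_um: float,
    strip_width_um: float,
    bleach_center_um: tuple,
    bleach_radius_um: float,
    bleach_depth: float,
    seed: int,
) -> np.ndarray:
    """Expected bleach-spot recovery from a particle-level random walk.

    Particles start uniform in a closed rectangle (reflective walls); a
    fraction ``mobile_fraction`` takes Gaussian steps of per-axis sd
    sqrt(2 D dt) each frame. At t=0 particles inside the bleach disc lose
    their fluorescence with probability ``bleach_depth``. Returns the
    in-disc fluorescent count per frame normalized as a recovery fraction
    f(t) = (N(t) - N(0)) / (N_pre - N(0)), with N_pre the pre-bleach
    expectation.
    """
    rng = np.random.default_rng(seed)
    pos = rng.uniform((0, 0), (strip_height_um, strip_width_um), size=(n_particles, 2))
    mobile = rng.random(n_particles) < mobile_fraction
    step_sd = np.sqrt(2.0 * diffusion_coeff * frame_interval_s)

    def in_disc(p):
        return (p[:, 0] - bleach_center_um[0]) ** 2 + (p[:, 1] - bleach_center_um[1]) ** 2 \
            <= bleach_radius_um ** 2

    fluorescent = np.ones(n_particles, dtype=bool)
    hit = in_disc(pos) & (rng.random(n_particles) < bleach_depth)
    fluorescent[hit] = False

    disc_area = np.pi * bleach_radius_um ** 2
    n_pre = n_particles * disc_area / (strip_height_um * strip_width_um)
    counts = np.empty(n_steps + 1)
    counts[0] = np.count_nonzero(fluorescent & in_disc(pos))
    hi = np.array([strip_height_um, strip_width_um])
    for s in range(1, n_steps + 1):
        steps = rng.normal(0.0, step_sd, size=(n_particles, 2))
        steps[~mobile] = 0.0
        pos = pos + steps
        # reflective walls (single fold suffices for small steps)
        pos = np.abs(pos)
        pos = hi - np.abs(hi - pos)
        counts[s] = np.count_nonzero(fluorescent & in_disc(pos))
    return (counts - counts[0]) / (n_pre - counts[0])


def brute_force_moments(frames: np.ndarray):
    """Per-pixel temporal mean and unbiased variance by explicit loops."""
    n, rows, cols = frames.shape
    mean = np.zeros((rows, cols))
    var = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            series = frames[:, r, c]
            mu = sum(series) / n
            mean[r, c] = mu
            var[r, c] = sum((s - mu) ** 2 for s in series) / (n - 1)
    return mean, var
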