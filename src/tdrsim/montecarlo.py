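"""Brute-force random-walk oracle for restricted diffusion in a single pore.

Spins perform an elastic-reflection random walk inside a cylinder cross
section (2-D disc; the axial dimension is free and handled analytically
elsewhere) or a sphere, accumulating phase under the rectangular SDE pulse
pair.  The signal is |⟨e^{iφ}⟩| over walkers.  This estimator is independent
of the GPD series and is used to validate it.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .sequences import GAMMA, SDEWaveform

__all__ = ["mc_oracle", "free_diffusion_mc", "ResolutionError"]


class ResolutionError(ValueError):
    """Step length too coarse relative to the pore size."""


@njit(cache=True)
def _walk_disc(radius, delta, Delta, G_gamma, D, n_walkers, n_steps, dt, seed):
    """Phase accumulation for walkers reflected inside a disc of ``radius``.

    G_gamma = γG in rad ms⁻¹ μm⁻¹; gradient along x during [0, δ] with +1 and
    [Δ, Δ+δ] with −1.  Returns (Σ cos φ, Σ sin φ).
    """
    np.random.seed(seed)
    sigma = math.sqrt(2.0 * D * dt)
    sum_c = 0.0
    sum_s = 0.0
    for w in range(n_walkers):
        # uniform start in the disc
        while True:
            x = (2.0 * np.random.random() - 1.0) * radius
            y = (2.0 * np.random.random() - 1.0) * radius
            if x * x + y * y <= radius * radius:
                break
        phase = 0.0
        for step in range(n_steps):
            t = step * dt
            if t < delta:
                g = 1.0
            elif Delta <= t < Delta + delta:
                g = -1.0
            else:
                g = 0.0
            x_old = x
            x += sigma * np.random.normal()
            y += sigma * np.random.normal()
            r = math.sqrt(x * x + y * y)
            if r > radius:
                # radial specular reflection back inside
                rr = 2.0 * radius - r
                if rr < 0.0:
                    rr = radius * np.random.random()
                x *= rr / r
                y *= rr / r
            if g != 0.0:
                # midpoint rule for the phase integral over this step
                phase += G_gamma * g * 0.5 * (x_old + x) * dt
        sum_c += math.cos(phase)
        sum_s += math.sin(phase)
    return sum_c, sum_s


@njit(cache=True)
def _walk_sphere(radius, delta, Delta, G_gamma, D, n_walkers, n_steps, dt, seed):
    """Same as :func:`_walk_disc` in 3-D inside a sphere."""
    np.random.seed(seed)
    sigma = math.sqrt(2.0 * D * dt)
    sum_c = 0.0
    sum_s = 0.0
    for w in range(n_walkers):
        while True:
            x = (2.0 * np.random.random() - 1.0) * radius
            y = (2.0 * np.random.random() - 1.0) * radius
            z = (2.0 * np.random.random() - 1.0) * radius
            if x * x + y * y + z * z <= radius * radius:
                break
        phase = 0.0
        for step in range(n_steps):
            t = step * dt
            if t < delta:
                g = 1.0
            elif Delta <= t < Delta + delta:
                g = -1.0
            else:
                g = 0.0
            x_old = x
            x += sigma * np.random.normal()
            y += sigma * np.random.normal()
            z += sigma * np.random.normal()
            r = math.sqrt(x * x + y * y + z * z)
            if r > radius:
                rr = 2.0 * radius - r
                if rr < 0.0:
                    rr = radius * np.random.random()
                x *= rr / r
                y *= rr / r
                z *= rr / r
            if g != 0.0:
                phase += G_gamma * g * 0.5 * (x_old + x) * dt
        sum_c += math.cos(phase)
        sum_s += math.sin(phase)
    return sum_c, sum_s


def mc_oracle(
    geometry: str,
    diameter: float,
    w: SDEWaveform,
    D: float = 2.0,
    n_walkers: int = 10_000,
    n_steps: int | None = None,
    seed: int = 0,
    return_se: bool = False,
):
    """Random-walk estimate of the restricted signal fraction in one pore.

    The gradient is perpendicular to the cylinder axis (cylinders restrict
    only transversally) or arbitrary for spheres.  The step length
    √(2 D dt) must not exceed diameter/10; by default ``n_steps`` is chosen
    to satisfy this with margin.  Returns |mean(e^{iφ})|, plus its standard
    error when ``return_se`` is set.
    """
    if geometry not in ("cylinder", "sphere"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    duration = w.Delta + w.delta
    if n_steps is None:
        # resolve both the pore (steps ≤ d/12) and, at strong gradients, the
        # dephasing length ℓ_g = (D/γG)^{1/3} (steps ≤ ℓ_g/8)
        length = diameter / 12.0
        if w.G > 0:
            ell_g = (D / (GAMMA * w.G)) ** (1.0 / 3.0)
            length = min(length, ell_g / 8.0)
        dt_max = length**2 / (2.0 * D)
        n_steps = max(200, int(math.ceil(duration / dt_max)))
    dt = duration / n_steps
    if math.sqrt(2.0 * D * dt) > diameter / 10.0:
        raise ResolutionError(
            f"step length {math.sqrt(2 * D * dt):.3g} μm exceeds diameter/10; "
            "increase n_steps"
        )
    kernel = _walk_disc if geometry == "cylinder" else _walk_sphere
    sum_c, sum_s = kernel(
        diameter / 2.0, w.delta, w.Delta, GAMMA * w.G, D, n_walkers, n_steps, dt,
        seed,
    )
    mean_c = sum_c / n_walkers
    mean_s = sum_s / n_walkers
    signal = math.hypot(mean_c, mean_s)
    if not return_se:
        return signal
    # standard error of the real part dominates (imaginary mean ~ 0)
    se = math.sqrt(max(1.0 - mean_c**2, 0.0) / n_walkers)
    return signal, se


def free_diffusion_mc(
    w: SDEWaveform,
    D: float = 2.0,
    n_walkers: int = 20_000,
    n_steps: int = 2000,
    seed: int = 0,
) -> float:
    """Unrestricted 1-D walk under the same pulse pair (closed form e^{−bD})."""
    rng = np.random.default_rng(seed)
    duration = w.Delta + w.delta
    dt = duration / n_steps
    t = np.arange(n_steps) * dt
    g = np.where(t < w.delta, 1.0, 0.0) - np.where(
        (t >= w.Delta) & (t < w.Delta + w.delta), 1.0, 0.0
    )
    steps = rng.normal(scale=math.sqrt(2.0 * D * dt), size=(n_walkers, n_steps))
    x = np.cumsum(steps, axis=1)
    x_mid = x - 0.5 * steps  # midpoint of each step interval
    phase = GAMMA * w.G * dt * (x_mid @ g)
    return float(abs(np.mean(np.exp(1j * phase))))
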