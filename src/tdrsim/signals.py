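"""Restricted-diffusion SDE signal synthesis (Gaussian phase distribution).

The attenuation of spins restricted in impermeable cylinders and spheres
under a rectangular pulse pair is computed with the Gaussian phase
distribution (GPD) series: for a pore of radius R and eigenvalues α_m,

    −ln S = 2 γ² G² Σ_m  B(D α_m²; δ, Δ) / [D² α_m⁶ w(α_m R)]

with the time factor

    B(a; δ, Δ) = 2aδ − 2 + 2e^{−aδ} + 2e^{−aΔ} − e^{−a(Δ−δ)} − e^{−a(Δ+δ)}

and, for cylinders, α_m R the roots of J₁′ and w(x) = x² − 1; for spheres,
α_m R the roots of j₁′ (spherical Bessel) and w(x) = x² − 2.  Cylinders
restrict only the transverse gradient component; diffusion along the axis is
free, so a tilted gradient contributes exp(−b D cos²θ) times the transverse
attenuation driven by G sinθ.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, special

from .sequences import GAMMA, SDEWaveform
from .substrates import OrientationSet, Substrate, discretise, watson_orientations

__all__ = [
    "ShellSignals",
    "cylinder_perp_attenuation",
    "sphere_attenuation",
    "cylinder_signal",
    "substrate_shell",
    "gpd_log_attenuation",
    "TruncationError",
]

_N_ROOTS = 40
_REL_TOL = 1e-8


class TruncationError(RuntimeError):
    """GPD series did not converge with the available eigenvalue roots."""


@lru_cache(maxsize=8)
def _cylinder_roots(n: int) -> np.ndarray:
    """First n positive roots of J₁′(x) = 0."""
    return special.jnp_zeros(1, n)


@lru_cache(maxsize=8)
def _sphere_roots(n: int) -> np.ndarray:
    """First n positive roots of j₁′(x) = 0 (spherical Bessel derivative)."""

    def j1p(x: float) -> float:
        return special.spherical_jn(1, x, derivative=True)

    roots: list[float] = []
    x, step = 1.0, 0.05
    f_prev = j1p(x)
    while len(roots) < n:
        x_next = x + step
        f_next = j1p(x_next)
        if f_prev == 0.0:
            roots.append(x)
        elif f_prev * f_next < 0:
            roots.append(optimize.brentq(j1p, x, x_next))
        x, f_prev = x_next, f_next
    return np.asarray(roots[:n])


def _time_factor(a: np.ndarray, delta: float, Delta: float) -> np.ndarray:
    """B(a; δ, Δ) for a = D α² (vectorised over a)."""
    return (
        2.0 * a * delta
        - 2.0
        + 2.0 * np.exp(-a * delta)
        + 2.0 * np.exp(-a * Delta)
        - np.exp(-a * (Delta - delta))
        - np.exp(-a * (Delta + delta))
    )


def gpd_log_attenuation(
    diameters: np.ndarray,
    delta: float,
    Delta: float,
    G: float,
    D: float,
    geometry: str,
    n_roots: int = _N_ROOTS,
) -> np.ndarray:
    """−ln S per diameter for a transverse (cylinder) or any (sphere) gradient.

    Vectorised over ``diameters`` (μm).  Raises :class:`TruncationError` if
    the last series term still contributes more than 1e-8 of the sum.
    """
    diameters = np.atleast_1d(np.asarray(diameters, dtype=float))
    if geometry == "cylinder":
        x = _cylinder_roots(n_roots)
        w = x**2 - 1.0
    elif geometry == "sphere":
        x = _sphere_roots(n_roots)
        w = x**2 - 2.0
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    R = diameters[:, None] / 2.0
    alpha = x[None, :] / R
    a = D * alpha**2
    terms = _time_factor(a, delta, Delta) / (D**2 * alpha**6 * w[None, :])
    total = terms.sum(axis=1)
    tail = np.abs(terms[:, -1])
    if np.any(tail > _REL_TOL * np.maximum(np.abs(total), 1e-300)):
        raise TruncationError(
            f"GPD series not converged with {n_roots} roots; "
            "increase n_roots for these diameters/timings"
        )
    return 2.0 * (GAMMA * G) ** 2 * total


def cylinder_perp_attenuation(
    diameter: float, w: SDEWaveform, D: float = 2.0
) -> float:
    """Signal fraction for a cylinder with the gradient perpendicular to it."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return float(
        np.exp(-gpd_log_attenuation(diameter, w.delta, w.Delta, w.G, D, "cylinder"))[0]
    )


def sphere_attenuation(diameter: float, w: SDEWaveform, D: float = 2.0) -> float:
    """Signal fraction for a sphere (orientation-independent)."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return float(
        np.exp(-gpd_log_attenuation(diameter, w.delta, w.Delta, w.G, D, "sphere"))[0]
    )


def cylinder_signal(
    diameter: float,
    axis,
    g_dir,
    w: SDEWaveform,
    D: float = 2.0,
) -> float:
    """Signal for a cylinder at arbitrary angle to the gradient.

    Free Gaussian diffusion along the axis (weighting b cos²θ) times the GPD
    transverse attenuation driven by the gradient component G sinθ.
    """
    axis = np.asarray(axis, dtype=float)
    g_dir = np.asarray(g_dir, dtype=float)
    cos_t = float(np.clip(axis @ g_dir, -1.0, 1.0))
    sin2 = 1.0 - cos_t**2
    lnS_perp = gpd_log_attenuation(
        diameter, w.delta, w.Delta, w.G, D, "cylinder"
    )[0] * sin2
    return float(np.exp(-w.b * D * cos_t**2 - lnS_perp))


@dataclass(frozen=True)
class ShellSignals:
    """Normalised per-direction signals of one acquisition shell.

    Noise-free synthesised signals lie in [0, 1]; ``noisy=True`` marks a
    shell holding Rician magnitudes, which may exceed 1 near full signal and
    are only required to be non-negative.
    """

    waveform: SDEWaveform
    directions: np.ndarray
    signals: np.ndarray
    noisy: bool = False

    def __post_init__(self) -> None:
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        sig = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "signals", sig)
        if dirs.shape[0] != sig.shape[0]:
            raise ValueError("one signal per direction required")
        if np.any(sig < 0):
            raise ValueError("signals must be non-negative")
        if not self.noisy and np.any(sig > 1 + 1e-12):
            raise ValueError("noise-free signals must lie in [0, 1]")

    def __len__(self) -> int:
        return self.signals.shape[0]


def _bundle_orientations(sub: Substrate) -> list[OrientationSet]:
    """Per-bundle orientation sets (point orientation unless dispersed)."""
    sets = []
    for ax in sub.bundle_axes:
        if sub.dispersion_kappa is None:
            sets.append(OrientationSet(np.array([ax]), np.array([1.0])))
        else:
            sets.append(
                watson_orientations(sub.dispersion_kappa, mean_axis=ax, n_samples=500)
            )
    return sets


def substrate_shell(
    sub: Substrate,
    w: SDEWaveform,
    dirs: np.ndarray,
    n_bins: int = 50,
) -> ShellSignals:
    """Per-direction normalised signal of a substrate under one waveform.

    The signal is the volume-weighted average over diameter bins, summed over
    fibre bundles with their volume fractions; Watson dispersion, when set,
    averages the cylinder response over a weighted orientation grid.  Sphere
    substrates are orientation-independent.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    wd = discretise(sub.distribution, sub.geometry, n_bins=n_bins)
    D = sub.diffusivity

    if sub.geometry == "sphere":
        lnS = gpd_log_attenuation(wd.diameters, w.delta, w.Delta, w.G, D, "sphere")
        s = float(wd.weights @ np.exp(-lnS))
        return ShellSignals(w, dirs, np.full(dirs.shape[0], s))

    # cylinders: per-diameter transverse log-attenuation at full G, scaled by
    # sin²θ per (orientation, direction) pair; free diffusion along the axis
    lnS_perp = gpd_log_attenuation(wd.diameters, w.delta, w.Delta, w.G, D, "cylinder")
    signals = np.zeros(dirs.shape[0])
    for frac, oset in zip(sub.bundle_fractions, _bundle_orientations(sub)):
        cos2 = np.clip(oset.vectors @ dirs.T, -1.0, 1.0) ** 2  # (n_orient, n_dir)
        sin2 = 1.0 - cos2
        # (n_diam, n_orient, n_dir) attenuation, weight-summed over diameters
        att = np.exp(
            -w.b * D * cos2[None, :, :] - lnS_perp[:, None, None] * sin2[None, :, :]
        )
        per_orient = np.tensordot(wd.weights, att, axes=(0, 0))  # (n_orient, n_dir)
        signals += frac * (oset.weights @ per_orient)
    return ShellSignals(w, dirs, np.clip(signals, 0.0, 1.0))
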