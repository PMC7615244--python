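"""Pore populations: diameter distributions, fibre bundles, orientation dispersion.

Substrates are collections of impermeable cylinders (axon-like, possibly in
several crossing bundles with Watson orientation dispersion) or spheres
(soma-like).  Diameter distributions are discretised into weighted bins where
each pore's contribution to the total signal is volume-weighted: ∝ d² for
cylinders (per unit length) and ∝ d³ for spheres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DiameterDistribution",
    "Substrate",
    "WeightedDiameters",
    "OrientationSet",
    "preset_substrates",
    "discretise",
    "truncation_mean_shift",
    "fibre_configuration",
    "watson_orientations",
]

#: Gamma distributions of cylinder diameters are cut at this diameter (μm)
#: to keep the tail within histologically plausible axon calibres.
GAMMA_TRUNCATION_UM = 20.0

#: Normal distributions are cut at ±4 standard deviations (and at zero).
NORMAL_TRUNCATION_SIGMAS = 4.0


@dataclass(frozen=True)
class DiameterDistribution:
    """Diameter distribution: family in {gamma, normal, delta}, mean/std in μm.

    For the gamma family the shape/scale parametrisation is recovered from
    (mean, std): shape = (mean/std)², scale = std²/mean.  ``truncation`` is
    the upper support bound for the gamma family (μm).
    """

    family: str
    mean: float
    std: float
    truncation: float = GAMMA_TRUNCATION_UM

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "normal", "delta"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("mean must be > 0")
        if self.std < 0:
            raise ValueError("std must be >= 0")

    @property
    def gamma_shape(self) -> float:
        return (self.mean / self.std) ** 2

    @property
    def gamma_scale(self) -> float:
        return self.std**2 / self.mean

    def pdf(self, d: np.ndarray) -> np.ndarray:
        """Un-truncated probability density over diameter."""
        d = np.asarray(d, dtype=float)
        if self.family == "gamma":
            return stats.gamma.pdf(d, a=self.gamma_shape, scale=self.gamma_scale)
        if self.family == "normal":
            return stats.norm.pdf(d, loc=self.mean, scale=self.std)
        raise ValueError("delta distribution has no density")

    def support(self) -> tuple[float, float]:
        """Truncated support [lo, hi] used for discretisation, μm."""
        if self.family == "delta" or self.std == 0:
            return (self.mean, self.mean)
        if self.family == "gamma":
            lo = max(1e-2, self.mean - 4.0 * self.std)
            return (lo, self.truncation)
        lo = max(1e-2, self.mean - NORMAL_TRUNCATION_SIGMAS * self.std)
        hi = self.mean + NORMAL_TRUNCATION_SIGMAS * self.std
        return (lo, hi)


@dataclass(frozen=True)
class WeightedDiameters:
    """Discretised distribution: bin-centre diameters (μm) and signal weights."""

    diameters: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "weights", w)
        if d.shape != w.shape:
            raise ValueError("diameters and weights must have the same shape")
        if np.any(d <= 0):
            raise ValueError("all diameters must be > 0")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")


@dataclass(frozen=True)
class Substrate:
    """Pore geometry + size distribution + (for cylinders) bundle geometry.

    ``bundle_axes`` are the mean fibre orientations (unit vectors, equal
    volume fractions unless ``bundle_fractions`` is given); ``dispersion_kappa``
    switches on Watson orientation dispersion about each axis.  Spheres carry
    no axes and are orientation-independent.
    """

    geometry: str
    distribution: DiameterDistribution
    bundle_axes: tuple = ()
    bundle_fractions: tuple = ()
    dispersion_kappa: float | None = None
    diffusivity: float = 2.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.geometry not in ("cylinder", "sphere"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be > 0")
        axes = tuple(tuple(float(x) for x in a) for a in self.bundle_axes)
        if self.geometry == "sphere":
            if axes:
                raise ValueError("sphere substrates carry no bundle axes")
        else:
            if not axes:
                axes = ((1.0, 0.0, 0.0),)
            for a in axes:
                n = np.linalg.norm(a)
                if abs(n - 1.0) > 1e-9:
                    raise ValueError(f"bundle axis {a} is not unit-norm")
        object.__setattr__(self, "bundle_axes", axes)
        fr = tuple(float(f) for f in self.bundle_fractions)
        if self.geometry == "cylinder":
            if not fr:
                fr = tuple(1.0 / len(axes) for _ in axes)
            if len(fr) != len(axes):
                raise ValueError("one volume fraction per bundle axis required")
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError("bundle fractions must sum to 1")
        object.__setattr__(self, "bundle_fractions", fr)


def preset_substrates() -> dict[str, Substrate]:
    """The four reference substrates, all with intrinsic diffusivity 2 μm²/ms.

    Gamma cylinder distributions mimic spinal-cord (large) and callosal
    (small) axon calibres; narrow normal sphere distributions mimic neuronal
    somas.
    """
    return {
        "small_cylinders": Substrate(
            geometry="cylinder",
            distribution=DiameterDistribution("gamma", mean=1.93, std=0.81),
            label="small_cylinders",
        ),
        "large_cylinders": Substrate(
            geometry="cylinder",
            distribution=DiameterDistribution("gamma", mean=5.33, std=3.00),
            label="large_cylinders",
        ),
        "small_spheres": Substrate(
            geometry="sphere",
            distribution=DiameterDistribution("normal", mean=7.0, std=0.5),
            label="small_spheres",
        ),
        "large_spheres": Substrate(
            geometry="sphere",
            distribution=DiameterDistribution("normal", mean=15.0, std=0.5),
            label="large_spheres",
        ),
    }


def discretise(
    dist: DiameterDistribution, geometry: str, n_bins: int = 50
) -> WeightedDiameters:
    """Discretise a diameter distribution into volume-weighted signal bins.

    Weights are ∝ pdf(d)·d² for cylinders and ∝ pdf(d)·d³ for spheres,
    evaluated at bin centres on the truncated support, then normalised.
    A degenerate distribution (delta family or std = 0) returns its single
    diameter with weight 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if geometry not in ("cylinder", "sphere"):
        raise ValueError(f"unknown geometry {geometry!r}")
    lo, hi = dist.support()
    if lo == hi:
        return WeightedDiameters(np.array([dist.mean]), np.array([1.0]))
    edges = np.linspace(lo, hi, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    power = 2 if geometry == "cylinder" else 3
    w = dist.pdf(centres) * centres**power
    total = w.sum()
    if total <= 0:
        raise ValueError("distribution has no mass on the truncated support")
    return WeightedDiameters(centres, w / total)


def truncation_mean_shift(dist: DiameterDistribution) -> float:
    """Relative change of the number-weighted mean caused by truncation.

    Grid cells where cutting the gamma tail at the truncation bound moves the
    mean by more than 10% are treated as inadmissible in the size-distribution
    sweeps (the truncated shape no longer represents the nominal distribution).
    """
    if dist.family != "gamma" or dist.std == 0:
        return 0.0
    a, scale = dist.gamma_shape, dist.gamma_scale
    t = dist.truncation
    mass = stats.gamma.cdf(t, a=a, scale=scale)
    if mass <= 0:
        return np.inf
    # E[X; X<t] = mean * P(Gamma(a+1, scale) < t)
    partial_mean = dist.mean * stats.gamma.cdf(t, a=a + 1, scale=scale)
    mean_trunc = partial_mean / mass
    return abs(mean_trunc - dist.mean) / dist.mean


def fibre_configuration(n_bundles: int) -> tuple[tuple[float, float, float], ...]:
    """1, 2 or 3 mutually orthogonal bundle axes (x; x,y; x,y,z)."""
    axes = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    if n_bundles not in (1, 2, 3):
        raise ValueError("n_bundles must be 1, 2 or 3")
    return axes[:n_bundles]


@dataclass(frozen=True)
class OrientationSet:
    """Weighted unit orientations approximating an orientation distribution."""

    vectors: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "weights", w)
        if v.shape[0] != w.shape[0] or v.shape[1] != 3:
            raise ValueError("vectors must be (n, 3) matching weights (n,)")


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = (i + 0.5) / n  # cosθ in (0, 1): upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``axis`` (any unit vector)."""
    axis = np.asarray(axis, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    c = float(axis @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def watson_orientations(
    kappa: float,
    mean_axis=(0.0, 0.0, 1.0),
    n_samples: int = 200,
    seed: int | None = None,
) -> OrientationSet:
    """Weighted orientation set for a Watson distribution of concentration κ.

    The Watson density on the sphere is ∝ exp(κ (μ·u)²), antipodally
    symmetric, concentrating around ±μ for large κ.  By default the set is a
    deterministic antipodally-symmetric quasi-uniform grid carrying density
    weights; passing a ``seed`` switches to rejection-free weighting of
    random uniform directions (reproducible given the seed).
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mean_axis = np.asarray(mean_axis, dtype=float)
    mean_axis = mean_axis / np.linalg.norm(mean_axis)

    if seed is None:
        half = max(1, n_samples // 2)
        upper = _fibonacci_hemisphere(half)
        pts = np.vstack([upper, -upper])
    else:
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    pts = pts @ _rotation_to(mean_axis).T
    cos2 = (pts @ mean_axis) ** 2
    w = np.exp(kappa * (cos2 - 1.0))  # shift by e^{-κ} for numerical range
    w /= w.sum()
    return OrientationSet(pts, w)
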