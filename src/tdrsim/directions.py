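"""Gradient direction sets: electrostatic-repulsion generation and presets.

HARDI shells sample many directions quasi-uniformly over the sphere.  The
classic construction minimises the Coulomb energy of antipodally symmetric
point pairs; the result is deterministic given the starting seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DirectionSet", "generate_directions", "minimum_angle"]


@dataclass(frozen=True)
class DirectionSet:
    """N unit 3-vectors (antipodally symmetric by convention)."""

    vectors: np.ndarray
    scheme: str = "repulsion"

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("direction vectors must be unit-norm (tol 1e-9)")
        object.__setattr__(self, "vectors", v)

    def __len__(self) -> int:
        return self.vectors.shape[0]


def coulomb_energy(v: np.ndarray) -> float:
    """Antipodally symmetric Coulomb energy Σ_{i<j} 1/|uᵢ−uⱼ| + 1/|uᵢ+uⱼ|."""
    n = v.shape[0]
    iu = np.triu_indices(n, k=1)
    d1 = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=2)[iu]
    d2 = np.linalg.norm(v[:, None, :] + v[None, :, :], axis=2)[iu]
    return float(np.sum(1.0 / np.maximum(d1, 1e-9) + 1.0 / np.maximum(d2, 1e-9)))


def _forces(v: np.ndarray) -> np.ndarray:
    """Net repulsive force on each point from all others and their antipodes."""
    diff = v[:, None, :] - v[None, :, :]
    summ = v[:, None, :] + v[None, :, :]
    d1 = np.maximum(np.linalg.norm(diff, axis=2), 1e-9)
    d2 = np.maximum(np.linalg.norm(summ, axis=2), 1e-9)
    np.fill_diagonal(d1, np.inf)
    f = (diff / d1[:, :, None] ** 3).sum(axis=1) + (summ / d2[:, :, None] ** 3).sum(
        axis=1
    )
    return f


def generate_directions(N: int, seed: int = 1234, maxiter: int = 500) -> DirectionSet:
    """Quasi-uniform antipodally-symmetric directions by Coulomb repulsion.

    Starting from a seeded random configuration, points move along the
    tangential component of the pairwise repulsive force (each point also
    repels every antipode) with a decaying step size; deterministic given
    (N, seed).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(N, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if N == 1:
        return DirectionSet(v)
    lr = 0.1 / N
    for it in range(maxiter):
        f = _forces(v)
        # project out the radial component to move along the sphere
        f -= (np.sum(f * v, axis=1, keepdims=True)) * v
        v = v + lr * f
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        if it and it % 100 == 0:
            lr *= 0.5
    return DirectionSet(v)


def minimum_angle(dirs: DirectionSet | np.ndarray) -> float:
    """Smallest pairwise angle (degrees), counting u and −u as identical."""
    v = dirs.vectors if isinstance(dirs, DirectionSet) else np.atleast_2d(dirs)
    n = v.shape[0]
    if n < 2:
        return 180.0
    dots = np.abs(v @ v.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))
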