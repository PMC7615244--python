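"""Gradient-waveform optimisation: maximise noise-free TDR at fixed b.

The search space is (δ₁, Δ₁, δ₂, Δ₂) with the amplitude of each shell solved
from the shared b-value, subject to G ≤ G_max, Δ+δ ≤ T_max and Δ ≥ δ.  Since
TDR = 1 − S₁/S₂ and each spherical-mean signal depends only on its own
shell's timings, the 4-D maximisation separates exactly: shell 1 minimises
the direction-averaged signal and shell 2 maximises it, each over its own
feasible (δ, Δ) box.  Both sub-problems are solved by an exhaustive coarse
grid followed by a Nelder–Mead polish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as sciopt

from .directions import generate_directions
from .sequences import (
    ScannerConstraints,
    SDEWaveform,
    check_constraints,
    gradient_for_b,
)
from .signals import substrate_shell
from .substrates import Substrate
from .tdr import spherical_mean, tdr

__all__ = [
    "OptimisationResult",
    "HARDWARE_SETS",
    "MIN_GAP",
    "objective",
    "optimise",
    "hardware_sweep",
    "non_optimised_pair",
]

#: The four scanner constraint sets explored: preclinical, high-gradient
#: preclinical, Connectome-class human, and high-performance clinical.
HARDWARE_SETS: dict[str, ScannerConstraints] = {
    "preclinical": ScannerConstraints(G_max=600.0, T_max=45.0),
    "preclinical_high": ScannerConstraints(G_max=2700.0, T_max=45.0),
    "connectome": ScannerConstraints(G_max=300.0, T_max=80.0),
    "clinical": ScannerConstraints(G_max=80.0, T_max=80.0),
}

_DELTA_MIN = 0.5  # ms; shortest pulse considered

#: Minimum gap Δ−δ between the two pulses (ms), leaving room for the
#: refocusing pulse of the spin echo; every published protocol respects it.
MIN_GAP = 2.0


@dataclass(frozen=True)
class OptimisationResult:
    """Optimised shell pair with the achieved TDR and search metadata."""

    shell1: SDEWaveform
    shell2: SDEWaveform
    tdr_opt: float
    s1_mean: float
    s2_mean: float
    constraints: ScannerConstraints
    b: float
    substrate_label: str
    trace: tuple = ()

    @property
    def signal_difference(self) -> float:
        """Direction-averaged S₂ − S₁ at the optimum."""
        return self.s2_mean - self.s1_mean


def _feasible(
    delta: float,
    Delta: float,
    c: ScannerConstraints,
    b: float,
    min_gap: float = MIN_GAP,
) -> bool:
    if delta < _DELTA_MIN or Delta < delta + min_gap or Delta + delta > c.T_max:
        return False
    return gradient_for_b(b, delta, Delta) <= c.G_max


def _mean_signal(substrate, delta, Delta, b, dirs, n_bins) -> float:
    w = SDEWaveform.from_b(b, delta, Delta)
    return spherical_mean(substrate_shell(substrate, w, dirs, n_bins=n_bins))


def objective(
    params,
    substrate: Substrate,
    constraints: ScannerConstraints,
    b: float,
    dirs: np.ndarray | None = None,
    n_bins: int = 30,
    penalty: float = -1e6,
    min_gap: float = MIN_GAP,
) -> float:
    """Noise-free TDR for timings (δ₁, Δ₁, δ₂, Δ₂); penalised if infeasible."""
    d1, D1, d2, D2 = (float(p) for p in params)
    if dirs is None:
        dirs = generate_directions(60, seed=1234).vectors
    if not (
        _feasible(d1, D1, constraints, b, min_gap)
        and _feasible(d2, D2, constraints, b, min_gap)
    ):
        return penalty
    s1 = _mean_signal(substrate, d1, D1, b, dirs, n_bins)
    s2 = _mean_signal(substrate, d2, D2, b, dirs, n_bins)
    return tdr(s1, s2)


def _grid_search(
    substrate, constraints, b, dirs, n_grid, n_bins, sign, min_gap
) -> tuple[float, float, float]:
    """Best (δ, Δ, signal) on the coarse grid; sign=+1 maximises the signal."""
    deltas = np.linspace(_DELTA_MIN, constraints.T_max / 2.0, n_grid)
    best = (np.nan, np.nan, np.nan)
    best_score = -np.inf
    for d in deltas:
        for D in np.linspace(d + min_gap, constraints.T_max - d, n_grid):
            if not _feasible(d, D, constraints, b, min_gap):
                continue
            s = _mean_signal(substrate, d, D, b, dirs, n_bins)
            if sign * s > best_score:
                best_score = sign * s
                best = (d, D, s)
    if not np.isfinite(best_score):
        raise ValueError("empty feasible region for these constraints and b")
    return best


def _polish(substrate, constraints, b, dirs, start, n_bins, sign, min_gap):
    """Nelder–Mead refinement of one shell's (δ, Δ) from the grid optimum."""

    def f(x):
        d, D = float(x[0]), float(x[1])
        if not _feasible(d, D, constraints, b, min_gap):
            return np.inf
        return -sign * _mean_signal(substrate, d, D, b, dirs, n_bins)

    res = sciopt.minimize(
        f,
        x0=np.asarray(start[:2]),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-10, "maxiter": 400},
    )
    if np.isfinite(res.fun):
        s_res = -res.fun * sign  # invert f = -sign * s
        if sign * s_res >= sign * start[2]:
            return float(res.x[0]), float(res.x[1]), s_res
    return start


def optimise(
    substrate: Substrate,
    constraints: ScannerConstraints,
    b: float = 8.0,
    n_grid: int = 40,
    refine: bool = True,
    n_dirs: int = 60,
    n_bins: int = 30,
    seed: int = 1234,
    min_gap: float = MIN_GAP,
) -> OptimisationResult:
    """Find the TDR-maximising shell pair under hardware constraints.

    Deterministic given the grid density and direction seed.  The returned
    ``tdr_opt`` is recomputed from the polished waveforms at full diameter
    resolution (50 bins).
    """
    dirs = generate_directions(n_dirs, seed=seed).vectors
    trace = []
    polished = []
    for sign in (-1.0, +1.0):  # shell 1 minimises S, shell 2 maximises S
        best = _grid_search(
            substrate, constraints, b, dirs, n_grid, n_bins, sign, min_gap
        )
        trace.append(("grid", sign, best))
        if refine:
            d, D, s = _polish(
                substrate, constraints, b, dirs, best, n_bins, sign, min_gap
            )
        else:
            d, D, s = best
        trace.append(("polish", sign, (d, D, s)))
        polished.append((d, D))

    w1 = SDEWaveform.from_b(b, *polished[0])
    w2 = SDEWaveform.from_b(b, *polished[1])
    s1 = _mean_signal(substrate, w1.delta, w1.Delta, b, dirs, 50)
    s2 = _mean_signal(substrate, w2.delta, w2.Delta, b, dirs, 50)
    for w in (w1, w2):
        report = check_constraints(w, constraints, rtol=1e-9)
        if not report:
            raise RuntimeError(f"optimiser returned infeasible waveform: {report}")
    return OptimisationResult(
        shell1=w1,
        shell2=w2,
        tdr_opt=tdr(s1, s2),
        s1_mean=s1,
        s2_mean=s2,
        constraints=constraints,
        b=b,
        substrate_label=substrate.label or substrate.geometry,
        trace=tuple(trace),
    )


def non_optimised_pair(
    constraints: ScannerConstraints,
    b: float = 8.0,
    min_gap: float = MIN_GAP,
) -> tuple[SDEWaveform, SDEWaveform]:
    """The originally proposed (non-optimised) shell pair for a constraint set.

    Both shells share the shortest feasible pulse duration δ (the minimum δ
    for which Δ = δ + gap keeps G within G_max); shell 1 takes the shortest
    diffusion time, shell 2 the longest allowed by T_max.
    """
    lo, hi = _DELTA_MIN, constraints.T_max / 2.0

    def g_at(delta: float) -> float:
        return gradient_for_b(b, delta, delta + min_gap)

    if g_at(hi) > constraints.G_max:
        raise ValueError("empty feasible region for these constraints and b")
    if g_at(lo) <= constraints.G_max:
        delta = lo
    else:
        delta = sciopt.brentq(lambda d: g_at(d) - constraints.G_max, lo, hi)
    w1 = SDEWaveform.from_b(b, delta, delta + min_gap)
    w2 = SDEWaveform.from_b(b, delta, constraints.T_max - delta)
    return w1, w2


def hardware_sweep(
    substrate: Substrate, b: float = 8.0, **kwargs
) -> dict[str, OptimisationResult]:
    """Optimise under each of the four scanner constraint sets."""
    return {
        name: optimise(substrate, c, b=b, **kwargs)
        for name, c in HARDWARE_SETS.items()
    }
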