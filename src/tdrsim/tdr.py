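"""TDR statistics: spherical means, sorted subsets, Rician noise ensembles.

TDR contrasts two direction-averaged shells acquired at the same b-value with
different gradient timings: TDR = (S₂ − S₁)/S₂.  For equal b, Gaussian
diffusion contributes identically to both shells, so nonzero TDR flags
time-dependent (restricted) diffusion.  TDR_M uses only the M gradient
directions with the highest mean signal (sorted on (S₁+S₂)/2), which
mitigates the Rician noise-floor bias from directions whose signal has
decayed into the floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signals import ShellSignals, substrate_shell
from .substrates import Substrate

__all__ = [
    "TDRResult",
    "NoiseSpec",
    "spherical_mean",
    "tdr",
    "tdr_subset",
    "tdr_subset_curve",
    "add_rician_noise",
    "tdr_noise_ensemble",
    "ensemble_curves",
    "cov_across_configs",
    "DegenerateSignalError",
]


class DegenerateSignalError(ValueError):
    """Raised when the reference signal S₂ is non-positive."""


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise ensemble: SNR on the b=0 signal, instance count, seed.

    Signals are normalised to the non-diffusion-weighted image, so the noise
    standard deviation per channel is σ = 1/SNR.  ``snr=math.inf`` means
    noise-free.
    """

    snr: float
    n_instances: int = 10_000
    seed: int = 1234

    def __post_init__(self) -> None:
        if not (self.snr > 0):
            raise ValueError("snr must be positive (use math.inf for noise-free)")
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")

    @property
    def sigma(self) -> float:
        return 0.0 if math.isinf(self.snr) else 1.0 / self.snr


@dataclass(frozen=True)
class TDRResult:
    """TDR value with its subset size and optional noise-ensemble statistics."""

    tdr: float
    subset_size: int
    n_directions: int
    ensemble_mean: float | None = None
    ensemble_std: float | None = None
    snr: float = math.inf

    def __post_init__(self) -> None:
        if not (1 <= self.subset_size <= self.n_directions):
            raise ValueError("subset size must satisfy 1 <= M <= N")


def spherical_mean(s: ShellSignals | np.ndarray) -> float:
    """Arithmetic mean of the per-direction signals (powder average)."""
    sig = s.signals if isinstance(s, ShellSignals) else np.asarray(s, dtype=float)
    if sig.size == 0:
        raise ValueError("empty shell")
    return float(np.mean(sig))


def tdr(s1_mean: float, s2_mean: float) -> float:
    """TDR = (S₂ − S₁)/S₂ from the two spherical-mean signals.

    May be negative (observed where signal decreases with diffusion time,
    e.g. exchange-dominated grey matter); values are not clipped.
    """
    if s2_mean <= 0:
        raise DegenerateSignalError(f"S2 mean must be > 0, got {s2_mean}")
    return (s2_mean - s1_mean) / s2_mean


def _sorted_signals(s1: np.ndarray, s2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort both shells by descending (S₁+S₂)/2; stable (index tie-break)."""
    order = np.argsort(-(s1 + s2) / 2.0, kind="stable")
    return s1[order], s2[order]


def tdr_subset(s1: ShellSignals, s2: ShellSignals, M: int) -> float:
    """TDR_M over the M directions with the highest mean signal.

    Directions are ranked by (S₁+S₂)/2 to stabilise the ordering against
    noise; TDR_M = (Σ_top-M S₂ − Σ_top-M S₁)/Σ_top-M S₂.  M = N recovers the
    plain spherical-mean TDR.
    """
    if len(s1) != len(s2) or not np.allclose(s1.directions, s2.directions):
        raise ValueError("shells must share the same direction set")
    N = len(s1)
    if not (1 <= M <= N):
        raise ValueError(f"M must satisfy 1 <= M <= {N}")
    a, b = _sorted_signals(s1.signals, s2.signals)
    return tdr(float(a[:M].sum()) / M, float(b[:M].sum()) / M)


def tdr_subset_curve(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """TDR_M for every M = 1..N at once (cumulative sorted sums)."""
    a, b = _sorted_signals(np.asarray(s1, float), np.asarray(s2, float))
    ca, cb = np.cumsum(a), np.cumsum(b)
    return (cb - ca) / cb


def add_rician_noise(s: ShellSignals, spec: NoiseSpec) -> ShellSignals:
    """One Rician noise instance: s ← |s + n₁ + i n₂|, n ~ N(0, σ=1/SNR)."""
    if spec.sigma == 0.0:
        return s
    rng = np.random.default_rng(spec.seed)
    noisy = _rician(s.signals, spec.sigma, rng)
    return ShellSignals(s.waveform, s.directions, noisy, noisy=True)


def _rician(signals: np.ndarray, sigma: float, rng: np.random.Generator,
            shape: tuple = ()) -> np.ndarray:
    full = shape + signals.shape
    n1 = rng.normal(scale=sigma, size=full)
    n2 = rng.normal(scale=sigma, size=full)
    return np.hypot(signals + n1, n2)


def _ensemble_tdr_curves(
    s1: np.ndarray,
    s2: np.ndarray,
    spec: NoiseSpec,
    gaussian: bool = False,
) -> np.ndarray:
    """(n_instances, N) array of TDR_M curves under seeded noise.

    ``gaussian`` adds real-valued Gaussian noise instead of taking the Rician
    magnitude (the real-valued-reconstruction scenario).
    """
    rng = np.random.default_rng(spec.seed)
    n, N = spec.n_instances, s1.shape[0]
    if spec.sigma == 0.0:
        s1n = np.broadcast_to(s1, (n, N)).copy()
        s2n = np.broadcast_to(s2, (n, N)).copy()
    elif gaussian:
        s1n = s1 + rng.normal(scale=spec.sigma, size=(n, N))
        s2n = s2 + rng.normal(scale=spec.sigma, size=(n, N))
    else:
        s1n = _rician(s1, spec.sigma, rng, shape=(n,))
        s2n = _rician(s2, spec.sigma, rng, shape=(n,))
    order = np.argsort(-(s1n + s2n) / 2.0, axis=1, kind="stable")
    c1 = np.cumsum(np.take_along_axis(s1n, order, axis=1), axis=1)
    c2 = np.cumsum(np.take_along_axis(s2n, order, axis=1), axis=1)
    return (c2 - c1) / c2


def ensemble_curves(
    s1: ShellSignals,
    s2: ShellSignals,
    spec: NoiseSpec,
    gaussian: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble mean and std of TDR_M for all M = 1..N."""
    curves = _ensemble_tdr_curves(s1.signals, s2.signals, spec, gaussian=gaussian)
    return curves.mean(axis=0), curves.std(axis=0)


def tdr_noise_ensemble(
    substrate: Substrate,
    shells: tuple,
    M: int,
    spec: NoiseSpec,
    dirs: np.ndarray | None = None,
    gaussian: bool = False,
) -> TDRResult:
    """Noise-ensemble statistics of TDR_M for one substrate and shell pair.

    ``shells`` is a pair of waveforms (or precomputed :class:`ShellSignals`);
    signals are synthesised once, then ``spec.n_instances`` noise draws are
    applied to both shells independently.
    """
    s1, s2 = _resolve_shells(substrate, shells, dirs)
    N = len(s1)
    if not (1 <= M <= N):
        raise ValueError(f"M must satisfy 1 <= M <= {N}")
    mean_curve, std_curve = ensemble_curves(s1, s2, spec, gaussian=gaussian)
    return TDRResult(
        tdr=tdr_subset(s1, s2, M),
        subset_size=M,
        n_directions=N,
        ensemble_mean=float(mean_curve[M - 1]),
        ensemble_std=float(std_curve[M - 1]),
        snr=spec.snr,
    )


def _resolve_shells(substrate, shells, dirs) -> tuple[ShellSignals, ShellSignals]:
    out = []
    for sh in shells:
        if isinstance(sh, ShellSignals):
            out.append(sh)
        else:
            if dirs is None:
                raise ValueError("dirs required when passing raw waveforms")
            out.append(substrate_shell(substrate, sh, dirs))
    return out[0], out[1]


def cov_across_configs(
    configs: list[Substrate],
    shells: tuple,
    spec: NoiseSpec,
    dirs: np.ndarray,
    pooled: bool = True,
) -> tuple[np.ndarray, int]:
    """Coefficient of variation of TDR_M across fibre configurations.

    For substrates sharing the same size distribution but different fibre
    geometry the noise-free TDR is identical, so the CoV-vs-M curve shows
    how the subset size trades precision (few directions, large noise
    scatter) against the Rician-floor bias (all directions, low-signal
    measurements included).  With ``pooled=True`` the CoV is taken over the
    noisy TDR_M estimates pooled across configurations and noise instances,
    so both sources of variability count; ``pooled=False`` uses only the
    ensemble means.  Returns the CoV for each M = 1..N and the minimising M.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations")
    curves = []
    for i, sub in enumerate(configs):
        s1, s2 = _resolve_shells(sub, shells, dirs)
        sub_spec = NoiseSpec(spec.snr, spec.n_instances, spec.seed + i)
        curves.append(_ensemble_tdr_curves(s1.signals, s2.signals, sub_spec))
    if pooled:
        arr = np.concatenate(curves, axis=0)
    else:
        arr = np.asarray([c.mean(axis=0) for c in curves])
    cov = arr.std(axis=0) / np.abs(arr.mean(axis=0))
    return cov, int(np.argmin(cov)) + 1
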