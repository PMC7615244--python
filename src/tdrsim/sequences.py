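"""Single diffusion encoding (SDE) waveforms and scanner hardware constraints.

Unit system used throughout the package: time in ms, length in μm, gradient
amplitude in mT/m, b-value in ms/μm², diffusivity in μm²/ms.  File readers and
writers convert at the boundary (FSL .bval files use s/mm²; Camino scheme
files use SI units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GAMMA",
    "SDEWaveform",
    "ScannerConstraints",
    "ProtocolPreset",
    "FeasibilityReport",
    "InvalidWaveformError",
    "bvalue",
    "gradient_for_b",
    "check_constraints",
    "protocol_presets",
]

#: Proton gyromagnetic ratio, 2.6752218744e8 rad s⁻¹ T⁻¹, expressed in
#: rad ms⁻¹ μm⁻¹ (mT/m)⁻¹ so that γ²G²δ²(Δ−δ/3) comes out in ms/μm².
GAMMA = 2.6752218744e-4


class InvalidWaveformError(ValueError):
    """Raised for non-physical pulse timings or amplitudes."""


def _validate_timings(delta: float, Delta: float) -> None:
    if not (delta > 0):
        raise InvalidWaveformError(f"pulse duration delta must be > 0, got {delta}")
    if Delta < delta:
        raise InvalidWaveformError(
            f"pulse separation Delta ({Delta}) must be >= delta ({delta})"
        )


def bvalue(delta: float, Delta: float, G: float) -> float:
    """Diffusion weighting b = γ²G²δ²(Δ−δ/3) of a rectangular SDE pair.

    Parameters
    ----------
    delta : float
        Gradient pulse duration δ, ms.
    Delta : float
        Pulse separation (diffusion time) Δ, ms; must satisfy Δ ≥ δ.
    G : float
        Gradient amplitude, mT/m; must be ≥ 0.

    Returns
    -------
    float
        b-value in ms/μm².
    """
    _validate_timings(delta, Delta)
    if G < 0:
        raise InvalidWaveformError(f"gradient amplitude must be >= 0, got {G}")
    return (GAMMA * G * delta) ** 2 * (Delta - delta / 3.0)


def gradient_for_b(b: float, delta: float, Delta: float) -> float:
    """Invert the b-value relation: the unique G ≥ 0 giving ``bvalue == b``."""
    _validate_timings(delta, Delta)
    if b < 0:
        raise InvalidWaveformError(f"b must be >= 0, got {b}")
    return math.sqrt(b / (Delta - delta / 3.0)) / (GAMMA * delta)


@dataclass(frozen=True)
class SDEWaveform:
    """One rectangular-pulse SDE pair (δ, Δ, G) with its derived b-value.

    ``b`` is always recomputed from the timings; constructing with an explicit
    ``b`` that disagrees with γ²G²δ²(Δ−δ/3) beyond 1e-9 relative raises.
    """

    delta: float
    Delta: float
    G: float
    b: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b_derived = bvalue(self.delta, self.Delta, self.G)
        if self.b is None:
            object.__setattr__(self, "b", b_derived)
        else:
            scale = max(abs(b_derived), 1e-30)
            if abs(self.b - b_derived) / scale > 1e-9:
                raise InvalidWaveformError(
                    f"stored b={self.b} inconsistent with timings (derived {b_derived})"
                )

    @classmethod
    def from_b(cls, b: float, delta: float, Delta: float) -> "SDEWaveform":
        """Build a waveform from timings with G solved from the target b."""
        return cls(delta=delta, Delta=Delta, G=gradient_for_b(b, delta, Delta))

    @property
    def duration(self) -> float:
        """Total encoding duration Δ+δ, ms."""
        return self.Delta + self.delta

    def scaled_gradient(self, factor: float) -> "SDEWaveform":
        """Same timings with the amplitude multiplied by ``factor``."""
        return SDEWaveform(delta=self.delta, Delta=self.Delta, G=self.G * factor)


@dataclass(frozen=True)
class ScannerConstraints:
    """Hardware feasibility box: max gradient G_max (mT/m), max Δ+δ (ms)."""

    G_max: float
    T_max: float

    def __post_init__(self) -> None:
        if self.G_max <= 0 or self.T_max <= 0:
            raise ValueError("G_max and T_max must be strictly positive")


@dataclass(frozen=True)
class FeasibilityReport:
    """Outcome of checking a waveform against a constraint set."""

    feasible: bool
    violations: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.feasible


def check_constraints(
    w: SDEWaveform, c: ScannerConstraints, rtol: float = 0.0
) -> FeasibilityReport:
    """Report every violated hardware bound (G ≤ G_max, Δ+δ ≤ T_max, Δ ≥ δ).

    ``rtol`` relaxes the amplitude and duration bounds by a relative margin,
    useful when checking printed protocol timings that were rounded.
    """
    violations: list[str] = []
    if w.G > c.G_max * (1.0 + rtol):
        violations.append(f"G={w.G:.6g} mT/m exceeds G_max={c.G_max:.6g} mT/m")
    if w.duration > c.T_max * (1.0 + rtol):
        violations.append(
            f"Delta+delta={w.duration:.6g} ms exceeds T_max={c.T_max:.6g} ms"
        )
    if w.Delta < w.delta:
        violations.append(f"Delta={w.Delta:.6g} < delta={w.delta:.6g}")
    return FeasibilityReport(feasible=not violations, violations=tuple(violations))


@dataclass(frozen=True)
class ProtocolPreset:
    """A named acquisition shell: label, waveform, target b, G_max context."""

    label: str
    waveform: SDEWaveform
    b_target: float
    G_max_context: float


# Published ex-vivo protocol timings: (shell label, b [ms/μm²], G_max context
# [mT/m]) -> (δ [ms], Δ [ms]).  Shell 1 is shared by the optimised and
# non-optimised pairs; shell 2n varies only Δ at the shell-1 δ; shell 2o uses
# the long-duration optimised waveform.
_PRESET_TIMINGS: dict[tuple[str, float, float], tuple[float, float]] = {
    ("shell1", 8.0, 600.0): (6.9, 9.0),
    ("shell1", 8.0, 2500.0): (2.2, 4.5),
    ("shell1", 20.0, 600.0): (9.7, 11.7),
    ("shell1", 20.0, 2500.0): (3.2, 5.2),
    ("shell2n", 8.0, 600.0): (6.9, 34.6),
    ("shell2n", 8.0, 2500.0): (2.2, 39.0),
    ("shell2n", 20.0, 600.0): (9.7, 32.0),
    ("shell2n", 20.0, 2500.0): (3.2, 38.5),
    ("shell2o", 8.0, 600.0): (14.0, 27.5),
    ("shell2o", 8.0, 2500.0): (15.0, 26.5),
    ("shell2o", 20.0, 600.0): (15.0, 26.5),
    ("shell2o", 20.0, 2500.0): (15.0, 26.5),
}


def protocol_presets() -> list[ProtocolPreset]:
    """All 12 published acquisition shells with G solved from each target b.

    Shells come in pairs at fixed b: (shell1, shell2n) is the non-optimised
    protocol (equal δ, longer Δ), (shell1, shell2o) the optimised protocol
    (long δ, low G for the second shell).
    """
    presets = []
    for (label, b, gmax), (delta, Delta) in _PRESET_TIMINGS.items():
        presets.append(
            ProtocolPreset(
                label=label,
                waveform=SDEWaveform.from_b(b, delta, Delta),
                b_target=b,
                G_max_context=gmax,
            )
        )
    return presets


def get_preset(label: str, b: float, G_max: float) -> ProtocolPreset:
    """Look up one published shell by label, b-value and G_max context."""
    key = (label, float(b), float(G_max))
    if key not in _PRESET_TIMINGS:
        raise KeyError(f"no preset {key}; available: {sorted(_PRESET_TIMINGS)}")
    delta, Delta = _PRESET_TIMINGS[key]
    return ProtocolPreset(
        label=label,
        waveform=SDEWaveform.from_b(b, delta, Delta),
        b_target=b,
        G_max_context=G_max,
    )
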