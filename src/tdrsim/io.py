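"""Reading and writing acquisition descriptions and signal tables.

Supported dialects:

* FSL ``.bval``/``.bvec``: one row of b-values in s/mm² (1 ms/μm² = 1000
  s/mm²) and three rows of unit direction components.
* Camino scheme: ``VERSION: STEJSKALTANNER`` with per-measurement rows
  ``x y z |G| Δ δ TE`` in SI units (T/m and s).
* Protocol YAML/JSON: a list of shells with keys
  ``{label, delta_ms, Delta_ms, b, G_mT_per_m}``.
* Signal tables: CSV with columns ``shell, dir_index, signal``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .directions import DirectionSet
from .sequences import ProtocolPreset, SDEWaveform
from .signals import ShellSignals
from .substrates import DiameterDistribution, Substrate

__all__ = [
    "write_bval_bvec",
    "read_bval_bvec",
    "write_camino_scheme",
    "read_camino_scheme",
    "write_protocol",
    "read_protocol",
    "write_substrate",
    "read_substrate",
    "write_signal_table",
    "read_signal_table",
    "ParseError",
]

#: 1 ms/μm² in s/mm².
BVAL_TO_SI = 1000.0


class ParseError(ValueError):
    """Malformed acquisition file; message carries the offending line."""


def write_bval_bvec(path_stem, bvals_ms_um2, dirs: DirectionSet | np.ndarray) -> None:
    """Write FSL-style ``<stem>.bval`` (s/mm²) and ``<stem>.bvec`` files."""
    stem = Path(path_stem)
    v = dirs.vectors if isinstance(dirs, DirectionSet) else np.atleast_2d(dirs)
    bvals = np.atleast_1d(np.asarray(bvals_ms_um2, dtype=float))
    if bvals.shape[0] != v.shape[0]:
        raise ValueError("one b-value per direction required")
    with open(stem.with_suffix(".bval"), "w") as fh:
        fh.write(" ".join(f"{b * BVAL_TO_SI:.6g}" for b in bvals) + "\n")
    with open(stem.with_suffix(".bvec"), "w") as fh:
        for row in v.T:  # 3 rows of N components
            fh.write(" ".join(f"{x:.9f}" for x in row) + "\n")


def read_bval_bvec(path_stem) -> tuple[np.ndarray, DirectionSet]:
    """Read FSL files, returning b in ms/μm² and the direction set."""
    stem = Path(path_stem)
    bvals = _read_rows(stem.with_suffix(".bval"), expect_rows=1)[0] / BVAL_TO_SI
    rows = _read_rows(stem.with_suffix(".bvec"), expect_rows=3)
    v = np.vstack(rows).T
    if v.shape[0] != bvals.shape[0]:
        raise ParseError(
            f"{stem}: bvec column count {v.shape[0]} != bval count {bvals.shape[0]}"
        )
    norms = np.linalg.norm(v, axis=1)
    bad = np.nonzero(np.abs(norms - 1.0) > 1e-6)[0]
    if bad.size:
        raise ParseError(f"{stem}.bvec: non-unit vector in column {bad[0] + 1}")
    return bvals, DirectionSet(v / norms[:, None], scheme="file")


def _read_rows(path: Path, expect_rows: int) -> list[np.ndarray]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append(np.array([float(tok) for tok in line.split()]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from exc
    if len(rows) != expect_rows:
        raise ParseError(f"{path}: expected {expect_rows} rows, found {len(rows)}")
    return rows


def write_camino_scheme(
    path, shells: list[tuple[SDEWaveform, DirectionSet]], TE_ms: float = 50.0
) -> None:
    """Write a Camino STEJSKALTANNER scheme (SI units: T/m, s)."""
    with open(path, "w") as fh:
        fh.write("VERSION: STEJSKALTANNER\n")
        for w, dirs in shells:
            v = dirs.vectors if isinstance(dirs, DirectionSet) else np.atleast_2d(dirs)
            for d in v:
                fh.write(
                    f"{d[0]:.9f} {d[1]:.9f} {d[2]:.9f} "
                    f"{w.G * 1e-3:.9g} {w.Delta * 1e-3:.9g} "
                    f"{w.delta * 1e-3:.9g} {TE_ms * 1e-3:.9g}\n"
                )


def read_camino_scheme(path) -> list[tuple[SDEWaveform, np.ndarray]]:
    """Read a Camino scheme, grouping consecutive rows with equal timings.

    Returns (waveform, directions) per group, in package units.
    """
    groups: list[tuple[SDEWaveform, list]] = []
    with open(path) as fh:
        header = fh.readline()
        if "STEJSKALTANNER" not in header:
            raise ParseError(f"{path}: line 1: expected STEJSKALTANNER header")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) != 7:
                raise ParseError(f"{path}: line {ln}: expected 7 fields")
            try:
                x, y, z, G, Delta, delta, _te = (float(t) for t in toks)
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from exc
            w = SDEWaveform(delta=delta * 1e3, Delta=Delta * 1e3, G=G * 1e3)
            if groups and _same_waveform(groups[-1][0], w):
                groups[-1][1].append((x, y, z))
            else:
                groups.append((w, [(x, y, z)]))
    return [(w, np.asarray(v)) for w, v in groups]


def _same_waveform(a: SDEWaveform, b: SDEWaveform) -> bool:
    return (
        abs(a.delta - b.delta) < 1e-9
        and abs(a.Delta - b.Delta) < 1e-9
        and abs(a.G - b.G) < 1e-6
    )


def write_protocol(path, presets: list[ProtocolPreset]) -> None:
    """Serialise shells to YAML (or JSON if the suffix is .json)."""
    payload = [
        {
            "label": p.label,
            "delta_ms": p.waveform.delta,
            "Delta_ms": p.waveform.Delta,
            "b": p.waveform.b,
            "G_mT_per_m": p.waveform.G,
            "G_max_context": p.G_max_context,
        }
        for p in presets
    ]
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def read_protocol(path) -> list[ProtocolPreset]:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    presets = []
    for entry in payload:
        w = SDEWaveform(
            delta=entry["delta_ms"], Delta=entry["Delta_ms"], G=entry["G_mT_per_m"]
        )
        presets.append(
            ProtocolPreset(
                label=entry["label"],
                waveform=w,
                b_target=entry.get("b", w.b),
                G_max_context=entry.get("G_max_context", float("nan")),
            )
        )
    return presets


def write_substrate(path, sub: Substrate) -> None:
    """Serialise a substrate description to YAML (mirrors the type fields)."""
    payload = {
        "geometry": sub.geometry,
        "distribution": {
            "family": sub.distribution.family,
            "mean": sub.distribution.mean,
            "std": sub.distribution.std,
            "truncation": sub.distribution.truncation,
        },
        "bundle_axes": [list(a) for a in sub.bundle_axes],
        "bundle_fractions": list(sub.bundle_fractions),
        "dispersion_kappa": sub.dispersion_kappa,
        "diffusivity": sub.diffusivity,
        "label": sub.label,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_substrate(path) -> Substrate:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    d = payload["distribution"]
    dist = DiameterDistribution(
        family=d["family"],
        mean=d["mean"],
        std=d["std"],
        truncation=d.get("truncation", 20.0),
    )
    return Substrate(
        geometry=payload["geometry"],
        distribution=dist,
        bundle_axes=tuple(tuple(a) for a in payload.get("bundle_axes", ())),
        bundle_fractions=tuple(payload.get("bundle_fractions", ())),
        dispersion_kappa=payload.get("dispersion_kappa"),
        diffusivity=payload.get("diffusivity", 2.0),
        label=payload.get("label", ""),
    )


def write_signal_table(path, shells: dict[str, ShellSignals]) -> None:
    """Per-shell, per-direction signals as a tidy CSV."""
    frames = []
    for label, sh in shells.items():
        frames.append(
            pd.DataFrame(
                {
                    "shell": label,
                    "dir_index": np.arange(len(sh)),
                    "signal": sh.signals,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_signal_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"shell", "dir_index", "signal"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
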