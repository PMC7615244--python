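# tdrsim

Simulation, statistics and acquisition optimisation for the **Temporal
Diffusion Ratio (TDR)** — a model-free diffusion-MRI contrast for restricted
diffusion, aimed at mapping large axons and cell bodies without fitting a
tissue model.

TDR contrasts two spherical-mean (powder-averaged) signals acquired at the
same, high b-value but with different gradient timings:

```
TDR = (S₂ − S₁) / S₂ ,          b = γ² G² δ² (Δ − δ/3)  fixed for both shells
```

Because the b-value is shared, Gaussian diffusion contributes equally to
both shells and cancels; restricted diffusion (in cylinders ≈ axons, or
spheres ≈ somas) makes the signal depend on the pulse timing, and TDR grows
with pore size.  The contrast is maximised by pairing a short-δ, high-G
shell with a long-δ, low-G shell.  Under Rician noise, computing the ratio
from the M highest-signal directions (TDR_M, sorted on (S₁+S₂)/2) avoids
the noise-floor bias of directions whose signal has decayed away.

The package provides:

* `tdrsim.sequences` — SDE waveforms, b-value algebra, scanner constraint
  checks, and the twelve published acquisition shells;
* `tdrsim.substrates` — gamma/normal pore-size distributions (volume-weighted
  discretisation), crossing fibre bundles, Watson orientation dispersion;
* `tdrsim.signals` — Gaussian-phase-distribution signal synthesis for
  cylinders and spheres, per gradient direction;
* `tdrsim.montecarlo` — an independent reflecting random-walk oracle used to
  validate the series engine;
* `tdrsim.tdr` — spherical means, TDR, sorted-subset TDR_M, Rician noise
  ensembles, cross-configuration variability;
* `tdrsim.optimise` — grid + Nelder–Mead maximisation of TDR over
  (δ₁, Δ₁, δ₂, Δ₂) at fixed b under G_max / timing constraints;
* `tdrsim.experiments`, `tdrsim.directions`, `tdrsim.io` — simulation
  runners, electrostatic-repulsion direction sets, FSL bval/bvec and Camino
  scheme IO, and a synthetic voxel phantom;
* a `tdrsim` command-line interface over all of the above.

## Worked example

Optimise the shell pair for a spinal-cord-like axon distribution
(gamma, mean 5.33 μm, std 3.00 μm, D = 2 μm²/ms) on a preclinical system
(G ≤ 600 mT/m, Δ+δ ≤ 45 ms) at b = 8 ms/μm², then examine the noise-floor
bias of the sorted-subset statistic at SNR 20:

```python
import numpy as np
from tdrsim import (ScannerConstraints, NoiseSpec, generate_directions,
                    optimise, preset_substrates, substrate_shell,
                    tdr_subset_curve)
from tdrsim.tdr import ensemble_curves

sub = preset_substrates()["large_cylinders"]
r = optimise(sub, ScannerConstraints(G_max=600, T_max=45), b=8.0)
print(f"shell1: delta={r.shell1.delta:.2f} ms, Delta={r.shell1.Delta:.2f} ms, "
      f"G={r.shell1.G:.0f} mT/m")
print(f"shell2: delta={r.shell2.delta:.2f} ms, Delta={r.shell2.Delta:.2f} ms, "
      f"G={r.shell2.G:.0f} mT/m")
print(f"noise-free TDR at the optimum: {r.tdr_opt:.3f}")

dirs = generate_directions(60, seed=1234).vectors
s1 = substrate_shell(sub, r.shell1, dirs)
s2 = substrate_shell(sub, r.shell2, dirs)
clean = tdr_subset_curve(s1.signals, s2.signals)
mean_c, _ = ensemble_curves(s1, s2, NoiseSpec(snr=20, n_instances=10_000, seed=42))
for M in (12, 60):
    print(f"TDR_{M}: noise-free {clean[M-1]:.3f}, SNR-20 ensemble mean "
          f"{mean_c[M-1]:.3f} ({100 * (1 - mean_c[M-1] / clean[M-1]):.1f}% low)")
```

Output:

```
shell1: delta=6.87 ms, Delta=8.87 ms, G=600 mT/m
shell2: delta=14.04 ms, Delta=30.96 ms, G=147 mT/m
noise-free TDR at the optimum: 0.573
TDR_12: noise-free 0.577, SNR-20 ensemble mean 0.564 (2.3% low)
TDR_60: noise-free 0.573, SNR-20 ensemble mean 0.428 (25.4% low)
```

The optimiser lands on the characteristic short-δ/high-G versus
long-δ/low-G pair; with noise, averaging all 60 directions costs a quarter
of the contrast while the top-12 subset loses only ~2%.

The same from the shell:

```sh
tdrsim optimise --substrate large_cylinders --b 8 --gmax 600 --tmax 45
tdrsim sim3 --snr 20 --out sim3.csv
```

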