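# Methods

## The measurement and the statistic

Single diffusion encoding (SDE) applies two rectangular gradient pulses of
duration δ, separation Δ and amplitude G; the diffusion weighting is
b = γ²G²δ²(Δ − δ/3) with γ the proton gyromagnetic ratio
(2.6752218744×10⁸ rad s⁻¹ T⁻¹; internally 2.6752218744×10⁻⁴
rad ms⁻¹ μm⁻¹ (mT/m)⁻¹ so that b comes out in ms/μm²).  All quantities in
the package use ms, μm, mT/m and μm²/ms; file readers and writers convert at
the boundary (FSL `.bval` files carry s/mm², Camino scheme files SI units).

The Temporal Diffusion Ratio contrasts two shells acquired at the same
(large) b with different timings:

    TDR = (S₂ − S₁) / S₂,

where S₁ and S₂ are spherical-mean (powder-average) signals over N gradient
directions.  At equal b, Gaussian diffusion contributes identically to both
shells, so TDR ≠ 0 isolates time-dependent — in practice restricted —
diffusion, and grows with pore size over the sensitive range.  The b-value
is fixed at 8 ms/μm² (high enough to suppress extra-cellular signal) and
the intra-pore diffusivity at 2 μm²/ms throughout; both are parameters.

The sorted-subset variant TDR_M ranks directions by the shell-average
signal (S₁+S₂)/2, descending, and evaluates the ratio on the top M sums.
Ranking on the average of the two shells, with ties broken by direction
index, keeps the ordering deterministic and less noise-sensitive than
ranking on a single shell.  M = N recovers the plain statistic.

## Signal engine

Restricted-diffusion attenuation is computed with the Gaussian phase
distribution (GPD) series for impermeable cylinders (transverse gradient
component) and spheres: eigenvalue roots of J₁′ (cylinder) and of the
spherical Bessel derivative j₁′ (sphere), weight factors x²−1 and x²−2
respectively, with the standard pulse-pair time factor.  Roots are cached;
40 roots are used and the series is declared non-converged (an error, not a
silent truncation) if the last term still contributes more than 1e-8 of the
sum.  Cylinders compose free axial diffusion exp(−bD cos²θ) with the
transverse restricted attenuation driven by G sinθ; spheres are
orientation-independent.

The GPD assumption (Gaussian spin-phase statistics) degrades at strong
attenuation in large pores.  A brute-force elastic-reflection random walk
inside a disc/sphere (`tdrsim.montecarlo`, numba-accelerated, midpoint
phase integration, step length bounded by both the pore size and the
gradient dephasing length (D/γG)^{1/3}) provides an independent estimate.
The two engines agree to better than 1.5% for diameters up to ~5 μm on all
twelve published shells; at 10 μm the true signal sits 5–9% below the GPD
value, and for the ultra-strong short pulses (2500 mT/m, δ ≈ 2–3 ms) GPD
is qualitatively wrong at large diameters (localisation regime).  The test
suite asserts the 3% band across the whole (shell × diameter) matrix so
that the cells where the Gaussian-phase assumption fails are visible as
failures rather than hidden.  On volume-weighted size distributions the
engines agree to better than 1% at the optimisation optima, because the
large-pore bins where GPD errs retain little signal.

## Substrates

Diameter distributions: gamma for cylinders (axon calibres; truncated at
20 μm, with grid cells rejected when truncation moves the nominal mean by
more than 10%), narrow normal for spheres (somas; support cut at ±4σ —
distributions used here have std ≤ 3 μm so the cut is immaterial).
Distributions are discretised into 50 bin centres by default; each bin's
signal weight is pdf(d)·d² for cylinders and pdf(d)·d³ for spheres
(volume weighting — large pores dominate the signal).  Moments are stable
to <0.5% under bin doubling.

Fibre geometry: one, two or three mutually orthogonal bundles with equal
volume fractions (configurable).  Orientation dispersion uses the Watson
distribution, weights ∝ exp(κ(μ·u)²), represented on a deterministic
antipodally symmetric golden-angle grid (500 points by default) for
reproducibility; a seeded random-orientation mode is retained.

## Waveform optimisation

The search space is (δ₁, Δ₁, δ₂, Δ₂) with each shell's G solved from the
shared b, under G ≤ G_max and Δ+δ ≤ T_max.  Because TDR = 1 − S₁/S₂ and
each spherical-mean signal depends only on its own shell, the 4-D
maximisation separates exactly: shell 1 minimises the mean signal, shell 2
maximises it, each over its own feasible (δ, Δ) box.  Both sub-problems use
an exhaustive 40×40 coarse grid followed by a Nelder–Mead polish; the
procedure is deterministic, cheap (~1 s per constraint set) and cannot be
trapped in the local optima an interior-point search over the joint 4-D
space is prone to on this corner-dominated landscape.

A minimum inter-pulse gap Δ − δ ≥ 2 ms is enforced by default: the spin
echo needs room for the refocusing pulse, and every published protocol
respects this margin.  Without it the short shell collapses to the δ = Δ
corner (δ ≈ 7.75 ms at 600 mT/m), which no scanner can play.  The gap is a
parameter (`min_gap`).  Slew rates are treated as infinite (rectangular
pulses); the constraint hook accepts a finite-rise-time extension but none
is implemented.

The optimum always contrasts a short-δ, high-G shell (feasibility corner of
the gradient bound) with a long-δ, low-G shell — at 600 mT/m and
Δ+δ ≤ 45 ms, shell 2 lands at (δ ≈ 14.0, Δ ≈ 31.0) ms for the large-axon
gamma distribution and (δ ≈ 16.3, Δ ≈ 28.7) ms for the small one.  Note the
exhaustive search attains a slightly higher optimal TDR under the weaker
clinical and Connectome constraint sets (≈0.12 and ≈0.49) than a local
4-D search does; the achieved maxima depend on where the short shell sits
on the gradient-bound boundary, and the landscape there is flat enough
that local searches stall a few percent short.

## Noise model and ensembles

Rician noise: s ← |s + n₁ + i n₂| with n₁, n₂ ~ N(0, σ) and σ = 1/SNR on
b0-normalised signals, drawn independently per direction and per shell.
Ensembles default to 10,000 instances (the bias and std of TDR_M are
converged to well under the reported differences at this size); every
ensemble is seeded.  The Rician floor σ√(π/2) biases low-signal directions
upward, which depresses TDR; TDR_M with small M excludes exactly those
directions.  With Gaussian (real-valued) noise instead, the full-set
statistic is unbiased — an ensemble test verifies this.

The cross-configuration analysis compares substrates with identical size
distributions but one, two or three orthogonal bundles.  The coefficient of
variation of TDR_M across configurations is taken over the noisy estimates
pooled across configurations and noise instances, so it combines
between-configuration disagreement with single-estimate precision; its
minimum (M ≈ 27 of 60 at SNR 20) is the subset size balancing the two.  A
means-only variant (`pooled=False`) isolates between-configuration
disagreement alone; that curve decreases monotonically with M for these
substrates, which is why the pooled definition is the default.

## Synthetic data

The phantom generator fills a labelled voxel grid with the analytic
per-substrate shell signals plus seeded Rician noise — a desk-scale
stand-in for an acquired 4-D volume (it can be written as NIfTI + bval/bvec
when nibabel is available).  It emulates per-voxel signal levels and noise,
but not spatial correlations, partial volume, relaxation differences,
exchange, or EPI artefacts: tests passing on the phantom demonstrate the
statistic pipeline (voxelwise sorting, subsetting, mapping), not robustness
to those real-data effects.

## Numerical choices and degenerate inputs

* Series truncation: 40 cached roots, 1e-8 relative tail bound, error on
  non-convergence.
* Degenerate size distribution (std = 0): a single diameter of weight 1.
* TDR with S₂ ≤ 0 raises; negative TDR values are returned unclipped
  (signal decreasing with diffusion time, as observed in exchange-dominated
  tissue, is representable).
* Sorting ties: stable sort, index order.
* Direction sets: antipodally symmetric electrostatic repulsion from a
  seeded start, 500 tangential-force iterations with decaying step; the
  Monte-Carlo oracle uses steps of at most diameter/12 and raises on
  coarser resolution.

## Known limitations

Intra-pore signal only — no extra-cellular compartment, tortuosity,
exchange, or relaxation weighting; single-coil Rician noise (no
non-central-χ); SDE rectangles only (no oscillating gradients or b-tensor
encoding); no eddy-current, concomitant-field or PNS modelling.  TDR is a
one-dimensional summary: distinct size distributions can share a TDR value,
and distributions with mean below ~3 μm at 600 mT/m sit near the resolution
limit where the contrast is a few percent at most — although heavy gamma
tails (std ≈ 1 μm at mean ≈ 3 μm) push the volume-weighted contrast above
0.1 even there.
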