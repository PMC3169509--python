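# Methods

## Measurement model

The scan is modeled as a discrete linear system `g = Φ f`. The image is an
N = n×n grid of pixel intensities centered at the origin with unit pixel
size; row index increases downward. A view at angle θ (degrees,
counter-clockwise from the x-axis) consists of B parallel rays with
direction (cos θ, sin θ), indexed by a perpendicular detector offset
`(b − (B−1)/2) · spacing` along (−sin θ, cos θ). Rays are zero-width lines;
`φ_ij` is the exact Euclidean length of the chord ray i cuts through pixel
j, so every stored weight lies in (0, √2] for unit pixels. Rays are ordered
view-major (`i = t·B + b`). Defaults: B = n bins at unit spacing, T views
evenly spaced over [0°, 180°).

Assumptions inherited from this model: monochromatic, non-refracting,
noise-free line integrals; no detector blur; 2-D slices only. These match
the simulation study the package ships; measured sinograms from real
scanners can be supplied as T×B arrays (CSV/TIFF) but the physics beyond
line integrals is out of scope.

## Projector

Chords are found by Siddon-style parametric traversal: entry/exit parameters
against the grid bounding box, then the sorted crossings with interior grid
lines; each segment's midpoint identifies its pixel and its parameter length
is the weight. Numerical details:

* segments shorter than 1e-12 pixel widths are discarded (they arise when a
  ray passes exactly through a lattice point and two crossings coincide to
  rounding);
* a ray lying exactly along a pixel boundary (possible only for
  axis-parallel rays) is assigned to the pixel on the positive-offset side —
  an arbitrary but deterministic tie-break;
* every ray is first canonicalized into the first octant (θ ∈ [0°, 45°],
  offset ≥ 0) by at most three index permutations of the dihedral symmetry
  group of the pixel grid (flip, transpose, point reflection). The
  symmetry-reusing builder caches canonical traces and distributes them to
  all congruent rays; the direct builder traces every ray through the same
  canonical routine. Both therefore produce bit-identical matrices, which
  the suite asserts exactly.

The matrix is stored as scipy CSR with cached squared row norms (the
Kaczmarz denominators). For the default 60-view/256-grid study it has
~4.7 M nonzeros (~60 MB) and builds in about two seconds; a versioned
binary cache format avoids re-tracing across runs.

## Phantom

The test object is the modified Shepp-Logan head phantom: ten additive
ellipses whose intensities are exact multiples of 0.1, rasterized at pixel
centers `(i − (n−1)/2) / ((n−1)/2)` with membership `≤ 1` (the Matlab
`phantom(n)` grid convention, y up). Intensities are accumulated in integer
tenths and divided by 10 once: plain float accumulation leaves ~1e-17
residue where the −0.8 and −0.2 ellipses should cancel the background,
which would destroy the exact-zero plateaus and hence the gradient-domain
sparsity the reconstruction method relies on. With exact cancellation the
256×256 phantom has 27 409 nonzero pixels and its gradient image 2 184 —
two orders of magnitude sparser, which is the property being exploited.
`count_nonzero` uses exact `≠ 0`, no epsilon.

The gradient image uses forward differences with out-of-grid differences
treated as zero, keeping it the same shape as the source.

## Reconstruction

**ART.** Relaxed Kaczmarz in natural view-major ray order (no randomized or
block ordering), `f(0) = 0`, rows with zero norm skipped. One call of
`art_sweep` is one complete pass over all M rays.

**TV-constrained solver.** Per cycle: one full ART sweep produces f(M);
`d = ‖f(M) − f(0)‖₂` measures the ART correction; then `n_tv_sub` steps of
`f ← f − α·d·v/‖v‖₂` where v is the gradient of the smoothed TV
`Σ sqrt(ε + |∇f|²)` (three-term subgradient with the same zero-boundary
convention; ε > 0 keeps the denominators finite). Design choices where the
procedure is genuinely open:

* `d` is computed once per cycle and held fixed across the sub-steps, while
  v is recomputed each sub-step — recomputing d inside the inner loop would
  couple the step length to the TV phase itself;
* the stopping metric is the per-pixel RMS change between successive cycles'
  post-sweep images, `‖f(M)_k − f(M)_{k−1}‖₂/√N < 0.001` on the working
  0–255 scale, or a cap of 1000 cycles; the returned image is the final
  post-sweep f(M), so with `n_tv_sub = 0` the solver is bit-identical to
  plain ART (asserted in the suite);
* ε appears only as the subgradient stabilizer (default 1e-4); the data-side
  tolerance is realized implicitly by the stopping rule;
* a non-negativity clamp is available but off by default;
* defaults λ = 1.0, α = 0.5, 5 sub-steps: the standard operating point of
  the study this package reproduces; they trade convergence speed against
  smoothing and are exposed everywhere (API, CLI, YAML config).

The sweep kernel is compiled with numba (sequential row updates cannot be
vectorized); everything else is numpy. No stage uses randomness, so results
are bit-reproducible; Gaussian sinogram noise, when enabled, is the single
seeded stochastic element.

**FBP.** Each view is zero-padded to the next power of two ≥ 2B, multiplied
by the Ram-Lak response 2|ν| in the frequency domain, backprojected with
linear interpolation at the per-pixel detector coordinate, and scaled by
π/(2T). Filter, interpolation and scaling follow the common discrete
convention (the same one scikit-image's `iradon` uses; the suite
cross-checks the two implementations on a shared sinogram). The scaling
assumes unit bin spacing.

## Metrics

RMSE, UQI and CC over the full image with N−1 normalized variance and
covariance, on the 0–255 working scale. CC is standard Pearson correlation:
the printed definition in the source study carries a stray factor of 2 that
would make CC(f, f) = 2, and all its reported values are ≤ 1, so the factor
is read as a typographical slip. UQI is the product of a correlation factor
and a luminance factor; both metrics raise a dedicated error on
zero-variance (constant) inputs rather than returning NaN.

## What the synthetic study does and does not show

The generator reproduces the study conditions exactly: noiseless sinograms
of the 0–255 phantom, simulated by the same exact-intersection projector
used inside the iterative solvers, at 60 and 30 evenly spaced views. Two
consequences must be kept in mind when reading the numbers:

* **Inverse crime.** Because simulation and reconstruction share one
  discrete forward model, the data are exactly consistent and the
  TV-constrained solver can recover the gradient-sparse phantom almost
  exactly (RMSE ~0.02 on 0–255 at 60 views). This is the correct behavior
  of the algorithm under these conditions, not a forecast for real data.
* **No physics.** Real projections carry noise, beam hardening, detector
  blur and model mismatch; with them the TV solver degrades gracefully
  rather than recovering exactly, and the margins between CS, ART and FBP
  shrink. The cross-method ordering (CS best, FBP worst at few views) is
  the robust qualitative finding; the absolute synthetic numbers are not.

Gaussian noise of configurable σ can be added to probe stability; the
default is σ = 0 because the study conditions state only that noise was
"minimal".

## Problem sizes

Unit and property tests run on 1–64-pixel grids where brute-force oracles
(dense line-integral sampling at 0.002 pixel, central-difference TV
gradients, scipy's Pearson, direct linear solves) are cheap and sharp. The
end-to-end suite and `scripts/acceptance.py` run the full 256×256, 60/30-view
study; a complete acceptance run takes about one minute on one CPU, dominated
by the two 1000-cycle TV-constrained reconstructions.

## Known limitations

Parallel-beam 2-D only (no fan/cone beam); zero-width rays (no strip or
footprint models); no ordered subsets or momentum acceleration; FBP scaling
assumes unit detector spacing; the TV phase uses plain normalized gradient
descent (no line search or primal-dual splitting), so its per-cycle descent
is only guaranteed for sufficiently small α·d.
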