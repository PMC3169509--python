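# sparsect

Sparse-view parallel-beam CT reconstruction in Python: a total-variation-
constrained algebraic reconstruction solver, with plain ART and filtered back
projection as references, an exact ray-driven projector, and the standard
image-quality metrics. The package is aimed at tomography and biomedical
imaging researchers who want to study how much projection data (and hence
dose and scan time) can be cut before reconstruction quality collapses — for
instance in synchrotron phase-contrast CT, where long scans can damage
biological specimens.

## The problem and the algorithm

A parallel-beam CT scan measures line integrals of an unknown image
*f* ∈ ℝ<sup>N</sup>:

```
g = Φ f,          φ_ij = length of the chord ray i cuts through pixel j
```

With few views (M ≪ N) this system is massively underdetermined and the
classical analytic inverse (FBP) produces severe streak artifacts.
Compressed sensing says recovery is still possible when the image is sparse
in some domain; piecewise-constant images are sparse in the *gradient*
domain, measured by the per-pixel forward-difference modulus

```
|∇f|_hw = sqrt( (f_{h+1,w} − f_{h,w})² + (f_{h,w+1} − f_{h,w})² )
```

whose l1-norm is the total variation. The solver alternates two phases per
cycle, starting from f = 0:

1. **Data consistency** — one full relaxed Kaczmarz (ART) sweep,
   `f ← f + λ (g_i − ⟨φ_i, f⟩) / ‖φ_i‖² · φ_i` for every ray in turn;
2. **Sparsity enforcement** — a few steps of gradient descent on the
   smoothed TV `Σ sqrt(ε + |∇f|²)`, with step length `α · d` tied to the
   size `d` of the ART correction so the two phases stay balanced.

Iteration stops when the per-pixel RMS change between successive post-sweep
images falls below a threshold, or at a cycle cap. With zero TV sub-steps
the method reduces exactly to plain ART. Reconstructions are scored against
the reference by RMSE, the universal quality index (UQI) and Pearson
correlation (CC), with N−1 normalized (co)variances.

The projector computes exact Euclidean chord lengths (Siddon-style
parametric traversal). Because parallel rays at angles α, 90°−α, 90°+α,
180°−α with mirrored offsets cut congruent chords, every ray is
canonicalized into the first octant and the system-matrix builder reuses
each traced ray across its eight-fold symmetry class.

## Worked example

```python
import sparsect as sc

phantom = sc.to_byte_scale(sc.generate_shepp_logan(256))   # 0-255 scale
sino, A = sc.simulate_sinogram(phantom, n_views=60)        # 60 views, 256 bins
result = sc.CSReconstruction(sino, A).fit()
print(result.summary())
report = sc.evaluate(result.image, phantom)
print(f"RMSE={report.rmse:.3f}  UQI={report.uqi:.4f}  CC={report.cc:.4f}")
```

prints

```
=========================================================================================
Reconstruction Results
=========================================================================================
Method                CS-based iteration
Image grid            256 x 256
Cycles run            1000
Converged             False
Final cycle change    0.00203588
Residual ||g - Af||   4.81405
Parameters            lambda=1.0 alpha=0.5 eps=0.0001 tv_sub=5 stop=0.001 max_cycles=1000
=========================================================================================
RMSE=0.021  UQI=1.0000  CC=1.0000
```

Reading it: from only 60 of the classical 180 views, and with noiseless data
simulated by the same exact projector, the TV-constrained solver drives the
data residual to ~5 (on sinogram entries of order 10⁴) and recovers the
gradient-sparse phantom essentially exactly — RMSE 0.021 on a 0–255 scale,
UQI and CC indistinguishable from 1. Under the same conditions plain ART
stalls at RMSE ≈ 16.5 and FBP at ≈ 22.8: the cross-method ordering
CS < ART < FBP (reversed for UQI/CC) is exactly the point of the method.

The same pipeline is available from the shell:

```
sparsect run-tables --out-dir results/      # full 60/30-view comparison
sparsect phantom --size 256 --out ph.tif
sparsect simulate --views 60 --out sino.tif
sparsect reconstruct --method cs --sinogram sino.tif --out rec.tif
sparsect evaluate --recon rec.tif --reference ph.tif --out report.json
```

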