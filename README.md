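# csmra

Optimization of Cartesian variable-density Poisson-disk undersampling for
compressed-sensing 3D time-of-flight MR angiography (TOF-MRA).

Highly accelerated TOF-MRA relies on undersampling the (k<sub>y</sub>,
k<sub>z</sub>) phase-encode plane and reconstructing with a sparsity prior.
The undersampling pattern is governed by three parameters: the acceleration
factor *R* (grid points per sampled point; scan time scales as 1/*R*), the
polynomial order *pp* of the sampling-density falloff (local density ∝
(1 − d)<sup>pp</sup> with *d* the normalized distance from the k-space
center; *pp* = 0 is homogeneous), and the side length *calib* of the fully
sampled central calibration block used to estimate coil sensitivities. At
matched scan time these parameters trade off against each other: every line
spent on a large calibration block is a line not spent on outer k-space,
where the high-frequency content of small vessels lives.

`csmra` provides the full retrospective-optimization pipeline on synthetic
multi-coil vessel phantoms, for researchers studying CS-MRA sampling design:

* **`csmra.phantom`** — sparse bright-vessel phantoms (large smooth tubes
  plus thin tortuous perforator-like vessels on a dim smooth background),
  smooth complex coil sensitivities, and simulated multi-coil k-space with
  complex Gaussian noise.
* **`csmra.sampling`** — variable-density Poisson-disk masks (Bridson-style
  with spatially varying exclusion radius, bisected to hit the requested
  *R* within 1%), mask characterization, and calibration scan-time
  accounting.
* **`csmra.recon`** — reconstruction by
  min<sub>x</sub> ½‖*M F S x* − *b*‖₂² + λ‖Φ*x*‖₁
  via FISTA (λ = 0.007, 20 iterations by default), with an orthogonal
  Daubechies-4 wavelet Φ and coil sensitivities estimated from the
  calibration block.
* **`csmra.metrics`** — maximum intensity projections normalized to the
  99th percentile, vessel masks, vessel-masked SSIM, and the
  peak-prominence vessel-visibility metric (100 left–right profiles over
  the central 50% of the FOV, prominence ≥ 0.15).
* **`csmra.sweep`** — the (R, pp, calib) grid search with per-cell
  deterministic seeding, aggregation, optimum selection, and the
  preliminary (λ, n_iter) reconstruction-parameter grid.
* **`csmra.io` / `csmra.cli`** — HDF5 k-space containers, NIfTI volumes,
  mask files, TOML sweep configs, run manifests, and a `csmra` command
  with `phantom`, `mask`, `undersample`, `recon`, `metrics`, and `sweep`
  subcommands.

## Worked example

```python
from csmra import (MaskParams, ReconConfig, calibration_cost_fraction,
                   make_coil_sensitivities, make_vessel_phantom, simulate_kspace)
from csmra.sweep import make_reference, evaluate_cell

shape = (64, 64, 64)
phantom = make_vessel_phantom(shape, n_large=2, n_small=6, seed=7)
sens = make_coil_sensitivities(shape, ncoils=8, seed=1)
kspace = simulate_kspace(phantom, sens, noise_sigma=0.01, seed=5)

reference = make_reference(kspace, calib_ref=32)
for R in (7.2, 15.0):
    cell = evaluate_cell(kspace, reference,
                         MaskParams(R=R, pp=2.0, calib=12, seed=0),
                         ReconConfig())
    print(f"R={R:4.1f}  achieved_R={cell['achieved_R']:.3f}  "
          f"ssim={cell['ssim']:.3f}  peaks={cell['n_peaks']} "
          f"(ref {reference.n_peaks}, change {cell['rel_peak_change']:+.1f}%)")
print(f"calibration scan-time saving 32->12: "
      f"{100*calibration_cost_fraction(32, 12):.0f}%")
```

prints

```
R= 7.2  achieved_R=7.199  ssim=0.917  peaks=55 (ref 54, change +1.9%)
R=15.0  achieved_R=15.004  ssim=0.757  peaks=47 (ref 54, change -13.0%)
calibration scan-time saving 32->12: 86%
```

Each line is one cell of the optimization grid: a Poisson-disk mask is
generated at the requested acceleration (achieved to within 1%), the fully
sampled k-space is retrospectively undersampled, coil sensitivities are
estimated from the mask's calibration block, the volume is reconstructed
with FISTA, and the result is scored against the fully sampled reference.
The vessel-masked SSIM (1 = perfect agreement) drops as acceleration grows,
and the detected-peak count falls below the reference (−13% at R = 15) as
small vessels fade — the degradations the sampling-parameter optimization
is designed to minimize. The last line is the scan-time accounting behind
preferring a 12 × 12 calibration block over the literature-standard
32 × 32: an 86% saving on the calibration region, reinvested in outer
k-space.

The same pipeline is scriptable from the shell:

```sh
csmra phantom --shape 64 64 64 --ncoils 8 --out k.h5
csmra mask generate --shape 64 64 --R 7.2 --pp 2.0 --calib 12 --seed 1 --out mask.h5
csmra undersample --kspace k.h5 --mask mask.h5 --out und.h5
csmra recon --kspace und.h5 --mask mask.h5 --lam 0.007 --iters 20 --out rec.nii.gz
```

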