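# Methods

This note documents the models, conventions, and numerical choices behind
`csmra`, and what its synthetic experiments do and do not show about real
acquisitions.

## Forward model and conventions

A 3D Cartesian acquisition samples lines along the readout axis k_x and
undersamples the (k_y, k_z) phase-encode plane. The multi-coil forward
model is

    b_c = M F (S_c ⊙ x) + n_c,

with x the complex image volume, S_c the receive sensitivity of coil c,
F the *centered orthonormal* FFT (DC at index N//2 per axis, unitary
scaling), M the binary sampling mask broadcast along coil and readout
axes, and n_c iid complex Gaussian noise, equal across coils. The
unitary FFT convention makes Parseval's identity and the forward/adjoint
dot-product test exact and keeps the regularization weight scale-stable.
Hermitian symmetry is not assumed; images may be complex.

## Vessel phantoms

Phantoms emulate the image statistics that make TOF-MRA compressible:
bright sparse vessels on a dim smooth background.

* **Large vessels** (radius 2–3 voxels): smooth tubes spanning the volume
  along a random principal axis with gentle sinusoidal wander.
* **Small vessels** (radius 0.6–1.2 voxels): thin tortuous tubes from a
  direction-perturbed random walk, smoothed; the `tortuosity` parameter
  scales the perturbation (default 1.0).
* **Rendering**: distance-to-centerline with a cosine-tapered edge whose
  half-width scales with the radius, `clip(r/2, 0.5, 1.5)` voxels. Thin
  vessels therefore stay near voxel caliber — important, because their
  k-space energy must extend far from the center, as it does for
  high-resolution angiograms. A fixed wide taper would blur them into
  multi-voxel blobs and concentrate nearly all spectral energy in the
  central k-space block, suppressing the role of outer k-space that the
  sampling optimization studies.
* **Background**: level 0.1 (in vessel-peak units) with low-frequency
  modulation bounded by that level. The in-vivo background after TOF
  saturation is not quantified in the literature we build on; 0.1 is a
  modeling choice.
* **Coil maps**: broad Gaussian magnitude lobes (σ = mean grid size, plus
  a 0.1 floor so the root-sum-of-squares never vanishes) centered on an
  ellipse around the volume, with gentle linear phase ramps. Per-voxel
  relative magnitude change stays below ~5% — much smoother than a real
  7 T array, which makes calibration-based sensitivity estimation easier
  than in vivo (see *Limitations*).
* **Noise**: σ = 0.01 per real/imaginary k-space component in the default
  fixtures — high-SNR, consistent with 7 T TOF.

All generators are pure functions of their arguments including the seed.

## Undersampling masks

Masks are variable-density Poisson-disk patterns with a fully sampled
central calib × calib block (centered on DC; the block spans
`N//2 − calib//2 … N//2 + ceil(calib/2) − 1` per axis).

* **Density law**: local sampling density ∝ (1 − d)^pp, the literal
  polynomial in the normalized elliptical distance d from DC;
  equivalently the local exclusion radius is r(d) = r0·(1 − d)^(−pp/2),
  with d capped at 0.98 so the radius stays finite at the grid edge.
  pp = 0 degenerates to homogeneous Poisson-disk sampling; larger pp
  concentrates samples near the center. (A flatter non-polynomial law of
  the form (1 + d)^(−pp) was evaluated and rejected: its center-to-edge
  density ratio of only 2^pp spreads samples into the energy-free corners
  of k-space and cannot reproduce the known behavior of variable-density
  masks at high acceleration.)
* **Sampler**: Bridson-style candidate propagation on the integer lattice,
  30 candidate attempts per active point; a candidate q is accepted when
  no existing sample s has dist(q, s) < min(r(q), r(s)), so a search
  window of half-width ceil(r(q)) suffices. The hot loop is numba-jitted;
  the generator is bit-reproducible per seed (masks are intended for
  prospective reuse).
* **Acceleration accounting**: R counts *all* sampled points including the
  calibration block, so masks at fixed (shape, R) are scan-time matched
  regardless of (pp, calib). r0 is found by bisection (≤ 40 generations)
  until the sample count reaches the target N/R; surplus samples are then
  removed uniformly at random, which cannot violate the minimum-distance
  property and makes counts — hence achieved R, within integer rounding —
  exact. Infeasible requests (calibration block alone exceeding the
  budget) raise an error naming the maximum feasible R.
* **Support**: the full rectangle of the phase-encode plane by default;
  elliptical corner exclusion is available as an option.

## Reconstruction

The reconstruction solves

    min_x  ½‖M F S x − b‖₂² + λ‖Φ x‖₁

with FISTA: gradient steps of fixed size 1/L (L from 30 power iterations
on AᴴA, seeded; L ≤ 1 under the unitary FFT with RSS-normalized
sensitivities), an exact proximal step (complex soft-thresholding of the
wavelet coefficients at λ/L), Nesterov momentum
t_{k+1} = (1 + √(1 + 4t_k²))/2, and the zero-filled adjoint Aᴴb as the
starting point. Defaults λ = 0.007 and n_iter = 20. The objective value
is recorded every iteration.

* **λ normalization**: k-space is scaled before reconstruction so the
  99th-percentile magnitude of the zero-filled adjoint image is 1;
  λ = 0.007 is defined on that scale, which makes the value portable
  across datasets. On the default noisy fixtures this λ is the interior
  optimum of {0.0007, 0.007, 0.07} and within fractions of a percent of
  the best SSIM over a (λ, n_iter) grid.
* **Wavelet**: Daubechies-4, 3 decomposition levels (clamped to the
  largest boundary-effect-free depth on small grids), periodization
  boundary handling — exactly orthonormal, so the soft-threshold prox is
  the exact minimizer, verified per coefficient against brute-force
  scalar minimization. Non-orthogonal wavelets are rejected.
* **Sensitivity estimation**: low-resolution autocalibration — the
  calibration block is Hann-apodized, zero-padded, inverse-FFT'd, and
  RSS-normalized with a small floor (1% of the peak RSS). This preserves
  the central trade-off (smaller blocks give coarser maps but free up
  scan time) at a fraction of the cost of a full eigen-decomposition
  autocalibration method, which is out of scope. On the default phantoms
  the mean magnitude error of the maps is < 0.005 inside the vessel
  support, with calib = 12 strictly worse than calib = 24 as expected.

## Quality metrics

* **MIPs** are per-pixel maxima along the projection axis (axial:
  head-foot; coronal: anteroposterior) and are normalized by their 99th
  intensity percentile before any scoring. Anteroposterior runs along
  image rows, left–right along columns.
* **Vessel-masked SSIM**: the standard SSIM map (Gaussian window σ = 1.5
  over an 11 × 11 support; stabilizers C1 = (0.01 L)², C2 = (0.03 L)²
  with dynamic range L = 1 after normalization, values clipped to [0, 1]
  for the SSIM computation only), averaged over a vessel mask built from
  the reference MIP: threshold 0.25, components < 5 px removed, then
  2-px dilation. Masking removes sensitivity to background variations.
  Note the 2-px dilation is calibrated to in-vivo MIP matrix sizes
  (hundreds of pixels); on very small projections (~64²) it dominates
  the mask area, so mask-sparsity expectations should be checked at
  ≥ ~96² grids.
* **Peak counting**: along n_lines = 100 left–right profiles spanning the
  central 50% of the anteroposterior extent (when the grid has fewer
  rows, one line per row), local maxima with topographic prominence
  ≥ 0.15 are counted; plateaus count once and endpoints are never peaks.
  The count is compared to the fully sampled reference as a percent
  change — the vessel-visibility surrogate robust to inter-scan motion
  that SSIM is not.

## Parameter sweep

For every (R, pp, calib) cell and mask replicate: generate the mask
(per-cell seed derived from `SeedSequence(seed_base, R, pp, calib,
replicate, crc32(volume_id))`, so any cell reruns bit-identically in
isolation), retrospectively undersample, estimate sensitivities from
that mask's calibration block, reconstruct, and score against the fully
sampled reference combined by the sensitivity-weighted adjoint — the same
coil-combination path the reconstructions use, so combination bias
cancels. Infeasible cells are recorded with their reason, never dropped.
Defaults: R ∈ {5, 7, 9, 11, 13, 15}, pp ∈ {0 … 2.8 step 0.4},
calib ∈ {10, 12, 16, 20, 24, 28, 32}, two masks per setting. Ties in
optimum selection break toward smaller calib, then smaller pp. Heatmaps
scale each acceleration's color range from its maximum mean SSIM down to
90% of that maximum.

## Problem sizes in the test suite

Unit tests run on 32³ volumes with 4 coils; the default desk-scale
fixture is 64³ with 8 coils. The calibration-size trend (calib 12 vs 32
at high R) runs on a (32, 128, 128) volume: a 128 × 128 phase-encode
plane is the smallest square plane that can host a 32 × 32 calibration
block at R = 15 under scan-time-matched accounting (a 64 × 64 plane
allows only ⌊4096/15⌉ = 273 samples, fewer than the block's 1024). The
trend fixture uses 4 large + 24 small vessels — vessel count scaled with
the in-plane FOV to mirror the vascular density of high-resolution
angiograms, whose small-vessel content is precisely what outer k-space
sampling preserves.

## Limitations

* No Bloch/inflow simulation of TOF contrast, motion, off-resonance, or
  eddy currents; the phantom reproduces sparsity and contrast statistics,
  not physiology.
* Synthetic coil maps are smoother than real arrays, so calibration-based
  sensitivity estimates are more accurate at any calib than in vivo; the
  cost side of the calibration-size trade-off is therefore understated.
* At low acceleration (R = 5) the large calibration block still scores
  marginally higher vessel-masked SSIM in these simulations, whereas
  in-vivo studies find the small block best at all accelerations; the
  desk-scale grids make the calibration block a much larger fraction of
  the sampling budget than on in-vivo matrices, which compresses the
  regime where the two effects trade off. The high-acceleration ordering
  and the growth of the small-block advantage with R do reproduce.
* Passing tests on these phantoms demonstrate correctness of the
  pipeline and sign-level reproduction of the sampling-design trends at
  desk scale, not quantitative agreement with any in-vivo measurement.
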