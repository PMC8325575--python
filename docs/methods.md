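# Methods

This note documents the models, numerical choices and limitations behind
`casct`.  Empirical statements here are limited to what the test suite and
`scripts/acceptance.py` themselves compute.

## Acquisition model

A 2D attenuation map `I(x, y)` (1/cm) on an N×N grid centered at the
rotation center is scanned by an equi-angular fan beam: the source rotates
at distance D from the center (angle β, counterclockwise from +y) and an
arc detector spans in-fan angles γ ∈ [−γ_max, +γ_max].  The fan ray
(β, γ) equals the parallel ray with normal angle α = β + γ and signed
offset ρ = D sin γ.  Defaults follow the simulated study protocol:
M = 360 views over a full rotation, 439 detector bins, D = 39.7 cm,
256×256 grids.  The fan half-angle is not part of the protocol; it is set
to `arcsin(fov/D) · 1.02` so the reconstruction circle is covered by every
view with a 2% margin, and the pixel pitch to `2·fov/N` with the field of
view chosen to inscribe the phantom support (default fov = 12.7 cm).
Monoenergetic Beer–Lambert physics with water at μ = 0.2/cm anchors the
Hounsfield scale; polyenergetic spectra and beam hardening are out of
scope because no spectrum enters any tested claim.

X-ray noise: each acquired ray draws counts from Poisson(I₀·exp(−S)) with
I₀ = 2×10⁷ photons and log-transforms back, clamping counts at 1 to avoid
infinities.  Noise applies pre-log (transmission domain) and only to
acquired views; unacquired rows are exactly zero.

## Projector

The forward projection is pixel-driven: for each view, every pixel center
is mapped to its fan coordinate γ(x, y, β), and the pixel's attenuation is
splatted onto the detector with total weight `pixel_area / (r·Δγ)`
(r = source-to-pixel distance), the consistent quadrature weight for a ray
wedge of angular width Δγ.  A plain two-bin linear splat aliases against
the regular pixel grid at the stated geometry (the pixel footprint spans
about 1.7 bins), so the splat integrates the pixel's projected angular
footprint — a box of width `pixel·(|cos ψ| + |sin ψ|)/r` around γ — against
the linear hat basis of the detector grid.  This keeps the operator
mass-preserving, exactly linear and exactly transposable.  For grids up to
128² the operator is materialized once per geometry as a sparse matrix
(fast repeated application during training); larger grids apply the same
weights on the fly.  `true_adjoint` is the literal transpose and is used
only to verify the inner-product identity; the *training* derivative of
projection is defined to be the FBP operator, *matching the unrolled
method's prescription rather than the adjoint*.

## FBP

Three linear stages.  (1) Rebinning to the parallel grid by bilinear
interpolation of `S(β, γ)` at β = α − γ, γ = arcsin(ρ/D), periodic in β,
zero outside the fan; the ρ grid reuses the detector bin count over
[−D sin γ_max, +D sin γ_max].  (2) Ram-Lak filtering per α row: FFT along
ρ, multiplication by |f| in physical frequency units (cycles/cm), inverse
FFT.  Rows are padded to a power of two at least 8× the row length: 2× is
needed against circular-convolution wrap, and the additional depth removes
the low-frequency bias of sampling |f| on a coarse DFT grid, which
otherwise costs about 2% interior RMSE at the full protocol.  The pad
segment bridges the circular gap linearly between the row endpoints, so a
constant row is annihilated exactly (DC response is exactly zero) while
physically supported rows — zero at both detector edges — reduce
bit-for-bit to zero-padding.  (3) Back-projection
`I(x,y) = (Δα/2)·Σ_i Ŝ(x cos α_i + y sin α_i, α_i)` with linear
interpolation along ρ; the 1/2 compensates double ray coverage over the
full 2π parallel set.  Missing views are zero-filled with no angular
reweighting, reproducing the artifact-laden naive baseline; short-scan
(Parker) weighting is deliberately not applied.  The derivative of FBP in
training is the forward projection.

Measured at the full protocol (`tests/test_acceptance.py`): disk
projections match the analytic chord length within 2% on interior rays,
and FBP∘FP of a 256² head phantom has ≤ 5% interior relative RMSE.

## Projection data fidelity layer

Acquisition is per view, so fidelity granularity is a whole view row.
Acquired rows are fused as `(λ·S_cnn + S_u)/(λ+1)` — the closed-form
minimizer of the quadratic sinogram fidelity with noise weight λ —
unacquired rows keep the prediction.  λ defaults to 0.001 (low-noise
setting); λ = 0 replaces measured rows exactly and is used in the
exactness tests.  One λ serves both the training objective and the layer.
The layer is parameter-free; its backward map is `Gfbp·D·G` where D scales
acquired rows by λ/(1+λ).  Because the fusion is linear and the
projection/FBP layers declare their surrogate derivatives, backpropagating
through the composed layer yields exactly this map.

## Network

See the README for the architecture.  Open choices and their resolutions:

* growth of the dense convolutions = 32 — reproduces the printed 0.51 M
  total with C = 32, 5 blocks, 4 dense convolutions (516,982 scalars,
  truncated at two decimals);
* channel-attention reduction = 2, from the stated bottleneck shapes
  (w₁ ∈ R^{C/2×C}, w₂ ∈ R^{C×C/2}); the bottleneck FC layers carry biases
  (does not change the truncated count);
* no activations on the two initial feature-extraction convolutions or the
  fusion convolutions (the block equations show bare convolutions);
  leaky-ReLU slope 0.01 on dense convolutions;
* a disabled attention branch passes the unattended fusion features
  through, so "no attention" reduces to a plain residual dense block;
* Kaiming fan-in initialization from a seeded generator (biases zero) for
  reproducibility.

The cascade shares one weight set across blocks (parameter count is
depth-independent), supervises only the final output, and does not clip
intermediate images.  "Adam momentum 0.99" is read as the first-moment
decay β₁ = 0.99, with β₂ = 0.999.  Network inputs are attenuation maps
linearly rescaled to [0, 1] over the configured HU window (default
[−1000, 1000] HU); the tomographic layers run in attenuation units with
the affine rescale wrapped around them (offsets cancel in the gradient).

All tensor machinery (convolutions, attention, Adam, the surrogate
derivative hooks) is a small reverse-mode autodiff on numpy arrays
(`casct.autodiff`), float64 throughout; gradients are verified against
finite differences in the test suite.

## Metrics

PSNR uses the HU window width as data range; SSIM uses the windowed
formulation with an 11-sample Gaussian window, σ = 1.5, and the standard
stabilization constants (via scikit-image); RMSE is reported in HU.
Identical images return an infinite-PSNR sentinel.

## Synthetic data: what it does and does not emulate

Phantoms are analytic ellipse compositions rasterized with 4× supersampled
coverage (anti-aliased edges): a head-like preset and seeded random
ellipse collections (a soft-tissue background disk inscribed in the field
of view plus 3–7 contrast ellipses in [−800, 1200] HU).  The ground truth
of every simulated item is the FBP of the full noiseless sinogram — the
reconstruction ceiling — not the phantom itself.  The simulator reproduces
the geometry, dose, and view-sampling protocols but none of the anatomy,
scatter, detector blur, bowtie filtration or polyenergetic physics of a
clinical scanner, so passing tests demonstrate the mechanics and the
relative benefit of the method on piecewise-constant objects, not clinical
image quality.

## Scaled-down study sizes

The trained-cascade checks run at sizes chosen for a single CPU: 64×64
grids, 111 detector bins, the full 360-view protocol with 1/4 sparse-view
sampling at 2×10⁷ photons, 100 training / 20 test phantoms, a Z = 2
cascade with an 8-channel 2-block backbone, 5 epochs of Adam at the
stated optimizer settings (batch 4), and a 200-step single-sample overfit
run at 32×32.  The acceptance thresholds at this scale are trend
properties (≥ 3 dB over the FBP input; per-block sinogram error
non-increasing on ≥ 90% of test items; ≥ 90% overfit loss drop), not the
full-scale benchmark numbers.

## Known limitations

* The surrogate derivatives (FBP for the projector and vice versa) are the
  method's definition, not the true adjoints; gradient-based training
  converges in practice but the loss gradient is inexact by construction.
* Zero-filled limited-view FBP loses a |Ω|/M amplitude factor by design;
  the cascade has to (and does) learn the rescaling.
* Fidelity is per view row; per-detector-bin masks are not supported.
* Fan geometry is 2D equi-angular with an arc detector only; no cone-beam,
  helical or flat-panel variants, and no short-scan weighting.
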