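# casct — limited-view fan-beam CT reconstruction

`casct` reconstructs tomographic images from **incomplete fan-beam
sinograms** — sparse-view acquisitions (every k-th projection view kept) and
limited-angle acquisitions (only a sector of the rotation covered) — both of
which cut radiation dose and scan time at the price of severe streak and
shading artifacts under plain filtered back-projection (FBP).  It is aimed
at researchers prototyping data-consistent deep reconstruction on CPU-scale
synthetic studies: every component, from the projector to the training
loop, runs on numpy and is exactly reproducible from a seed.

## Method

The core is **CasRedSCAN**, an unrolled cascade that alternates a learned
de-aliasing step with an analytic data-consistency step, mirroring the
regularization / fidelity alternation of model-based iterative
reconstruction:

* **RedSCAN** — a fully convolutional residual dense network with
  spatial-channel attention.  Initial feature extraction (two 3×3
  convolutions), n residual dense attention blocks (four densely connected
  3×3 convolutions, 1×1 local feature fusion, channel attention
  `v̂ = σ(w₂ η(w₁ v))` on the pooled channel vector and spatial attention
  `m̂ = σ(w₃ ⊛ F)` on a 1×1-squeezed map, fused additively, plus a local
  residual), global feature fusion over all block outputs and a global
  residual.  At the stated configuration (C = 32, 5 blocks, growth 32) it
  has **0.51 M parameters**.
* **PDFL** — the projection data fidelity layer.  The network output is
  forward projected onto the full view grid; acquired view rows `i ∈ Ω` are
  fused with the measured sinogram by the closed-form rule
  `S_rec(i) = (λ S_cnn(i) + S_u(i)) / (λ + 1)` (unacquired rows keep the
  prediction), and the fused sinogram is filtered back-projected.  With
  λ = 0 the measured data are restored exactly.  The layer has no learnable
  parameters; its backward map is `Gfbp · D · G`.
* **Differentiable operators** — a pixel-driven fan-beam projector `G`
  (equi-angular arc detector) and an FBP operator `Gfbp` (fan→parallel
  rebinning via α = β + γ, ρ = D sin γ; Ram-Lak filtering; back-projection).
  In training, the derivative of `G` is defined as `Gfbp` and vice versa.
* **Simulator** — analytic ellipse phantoms, Beer–Lambert transmission with
  Poisson counting noise (2×10⁷ incident photons per ray), 360 uniformly
  spaced views, 439 detector bins, 39.7 cm source-to-center distance, and
  the sparse-view (1/2, 1/4, 1/6) and limited-angle (0–90°, 0–120°, 0–150°)
  protocols.

Training minimizes the L2 loss between the final cascade output and the
full-view FBP ground truth with Adam (β₁ = 0.99, lr 5·10⁻⁴, batch 4); all
cascade blocks share one set of weights.

## Worked example

```python
import numpy as np
from casct import (
    AcquisitionProtocol, PhantomSpec, make_fan_geometry, make_phantom,
    simulate_acquisition, sample_views, evaluate,
)

geometry = make_fan_geometry(image_side=256, n_views=360, n_detectors=439,
                             source_distance=39.7, fov_radius=12.7)
phantom = make_phantom(PhantomSpec(kind="shepp_logan_like"), geometry)
protocol = AcquisitionProtocol(mode="sparse_view", sv_factor=4)

s_u, i_u = simulate_acquisition(phantom, protocol, geometry, seed=1)
print("acquired views:", len(sample_views(protocol, geometry)))

(metrics,) = evaluate([(i_u, phantom)])
print(f"sparse-view FBP: PSNR {metrics['psnr']:.2f} dB, "
      f"SSIM {metrics['ssim']:.3f}, RMSE {metrics['rmse']:.1f} HU")
```

prints

```
acquired views: 90
sparse-view FBP: PSNR 16.67 dB, SSIM 0.457, RMSE 293.3 HU
```

The 1/4 sparse-view scan keeps 90 of 360 views; naive FBP of the
zero-filled sinogram loses most of the signal amplitude and is overlaid
with streaks (16.7 dB against the phantom, RMSE 293 HU over the ±1000 HU
window).  The same pipeline on the full noiseless scan reaches 35.5 dB /
SSIM 0.987 / 33.5 HU, which is the reconstruction ceiling of the analytic
FBP chain at this geometry.  Training the cascade closes much of that gap:
`tests/test_acceptance.py` trains a Z = 2 cascade on one hundred 64×64
sparse-view scans and verifies a ≥ 3 dB PSNR gain over the FBP input, with
the per-block sinogram error decreasing through the cascade.

The same steps are available from the shell:

```sh
casct simulate --out data.h5 --mode sparse_view --sv-factor 4 --seed 1
casct train --data data.h5 --out model.npz
casct project --image phantom.npy --out sino.h5       # attenuation map -> sinogram
casct reconstruct --sinogram sino.h5 --method fbp --out rec.npy
casct evaluate --pred rec.npy --truth phantom.npy
```

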