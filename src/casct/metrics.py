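"""Reconstruction quality metrics: PSNR (dB), SSIM, RMSE (HU).

All three compare a reconstruction with the full-view reference after
conversion to Hounsfield units.  PSNR uses the configured HU display
window width as its data range; SSIM uses the windowed formulation with an
11-sample Gaussian window (sigma = 1.5) and the standard stabilization
constants; RMSE is reported directly in HU.  Identical inputs yield
RMSE = 0, SSIM = 1 and an infinite PSNR sentinel.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from .errors import ContractError
from .geometry import Image, mu_to_hu

#: display window used throughout unless overridden, HU
DEFAULT_HU_WINDOW = (-1000.0, 1000.0)


def _as_hu(img) -> np.ndarray:
    if isinstance(img, Image):
        return img.to_hu()
    return np.asarray(img, dtype=float)


def image_metrics(
    recon,
    reference,
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> dict[str, float]:
    """PSNR/SSIM/RMSE for one (reconstruction, reference) pair.

    ``Image`` inputs are attenuation maps converted to HU; bare arrays are
    taken to be in HU already.
    """
    a, b = _as_hu(recon), _as_hu(reference)
    if a.shape != b.shape:
        raise ContractError("reconstruction and reference shapes differ")
    rng = float(hu_window[1] - hu_window[0])
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if rmse == 0.0:
        return {"psnr": float("inf"), "ssim": 1.0, "rmse": 0.0}
    psnr = float(peak_signal_noise_ratio(b, a, data_range=rng))
    ssim = float(
        structural_similarity(
            b, a, data_range=rng, gaussian_weights=True, sigma=1.5, win_size=11
        )
    )
    return {"psnr": psnr, "ssim": ssim, "rmse": rmse}


def evaluate(
    pairs,
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> list[dict[str, float]]:
    """Per-image metrics over an iterable of (reconstruction, reference)."""
    return [image_metrics(r, t, hu_window) for r, t in pairs]
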