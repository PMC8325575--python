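"""Differentiable fan-beam forward projection.

The forward operator is pixel-driven: each image pixel is mapped to its
in-fan detector coordinate ``gamma(x, y, beta)`` and its attenuation is
splatted onto the nearby detector bins.  The splat models the pixel as a
box of its projected angular footprint (width ``pixel_size * (|cos psi| +
|sin psi|) / r_p`` with ``psi`` the ray normal angle and ``r_p`` the
source-to-pixel distance) integrated against the linear hat basis of the
detector grid, so it is mass-preserving and free of grid-beat aliasing.
The total weight per pixel is ``pixel_area / (r_p * dgamma)``, which makes
the bin sum a consistent discretization of the ray line integral (a wedge
of angular width ``dgamma`` at distance ``r`` from the source has physical
width ``r * dgamma``).

For small grids (up to ``_MATRIX_MAX_SIDE``) the operator is assembled once
per geometry as a sparse matrix — exactly linear, exactly transposable
(``true_adjoint``), and cheap to apply repeatedly inside the training loop.
Larger grids apply the identical per-view splat on the fly to bound memory.

The *training* derivative of the forward projection is, by construction of
the method, the filtered back-projection operator rather than the true
adjoint; ``true_adjoint`` is provided for verification only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ContractError
from .geometry import FanGeometry, Image, pixel_centers

#: largest image side for which the sparse operator matrices are cached
_MATRIX_MAX_SIDE = 128

_CACHE_ATTR = "_casct_op_cache"


def _op_cache(geometry: FanGeometry) -> dict:
    cache = getattr(geometry, _CACHE_ATTR, None)
    if cache is None:
        cache = {}
        object.__setattr__(geometry, _CACHE_ATTR, cache)
    return cache


@dataclass
class FanSinogram:
    """Line integrals on the (view, detector-bin) grid, dimensionless mu*cm."""

    values: np.ndarray
    geometry: FanGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_views_full, self.geometry.n_detector_bins)
        if self.values.shape != expected:
            raise ContractError(
                f"sinogram shape {self.values.shape} != geometry grid {expected}"
            )


def _hat_cdf(v: np.ndarray) -> np.ndarray:
    """Antiderivative of the unit hat ``max(0, 1 - |v|)``."""
    v = np.clip(v, -1.0, 1.0)
    return np.where(v <= 0, 0.5 * (v + 1.0) ** 2, 1.0 - 0.5 * (1.0 - v) ** 2)


def _view_splat(
    geometry: FanGeometry, beta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Splat table for one view: (detector bins, pixel indices, weights)."""
    nbins = geometry.n_detector_bins
    d = geometry.source_to_center
    dgamma = geometry.gamma_spacing
    gmax = geometry.fan_half_angle
    area = geometry.pixel_size ** 2

    X, Y = pixel_centers(geometry)
    x, y = X.ravel(), Y.ravel()
    sx, sy = -d * np.sin(beta), d * np.cos(beta)
    relx, rely = x - sx, y - sy
    # central-ray axis and its +gamma transverse direction
    along = relx * np.sin(beta) - rely * np.cos(beta)
    trans = relx * np.cos(beta) + rely * np.sin(beta)
    gamma = np.arctan2(trans, along)
    r = np.hypot(along, trans)
    w = area / (r * dgamma)
    cols_base = np.arange(x.size)

    if nbins == 1:
        ok = np.abs(gamma) <= max(gmax, dgamma)
        return np.zeros(ok.sum(), dtype=np.int64), cols_base[ok], w[ok]

    u = (gamma + gmax) / dgamma
    # projected angular half-footprint of the square pixel, in bin units
    psi = beta + gamma
    half = np.maximum(
        geometry.pixel_size
        * (np.abs(np.cos(psi)) + np.abs(np.sin(psi)))
        / (2.0 * r * dgamma),
        1e-6,
    )
    kmin = np.ceil(u - half - 1.0).astype(np.int64)
    ntaps = int(np.ceil(2.0 * half.max())) + 2
    bins_parts, cols_parts, data_parts = [], [], []
    for tap in range(ntaps):
        k = kmin + tap
        frac = (_hat_cdf(u + half - k) - _hat_cdf(u - half - k)) / (2.0 * half)
        wt = w * frac
        ok = (k >= 0) & (k < nbins) & (wt > 0)
        bins_parts.append(k[ok])
        cols_parts.append(cols_base[ok])
        data_parts.append(wt[ok])
    return (
        np.concatenate(bins_parts),
        np.concatenate(cols_parts),
        np.concatenate(data_parts),
    )


def uses_matrix(geometry: FanGeometry) -> bool:
    return geometry.image_side <= _MATRIX_MAX_SIDE


def fp_matrix(geometry: FanGeometry) -> sp.csr_matrix:
    """Sparse pixel-driven forward projector, (M*n_bins) x (N*N)."""
    cache = _op_cache(geometry)
    if "fp" in cache:
        return cache["fp"]
    n = geometry.image_side
    nbins = geometry.n_detector_bins
    rows_parts, cols_parts, data_parts = [], [], []
    for i, beta in enumerate(geometry.view_angles):
        bins, cols, wts = _view_splat(geometry, beta)
        rows_parts.append(i * nbins + bins)
        cols_parts.append(cols)
        data_parts.append(wts)
    mat = sp.csr_matrix(
        (
            np.concatenate(data_parts),
            (np.concatenate(rows_parts), np.concatenate(cols_parts)),
        ),
        shape=(geometry.n_views_full * nbins, n * n),
    )
    cache["fp"] = mat
    return mat


def _check_image(image: Image, geometry: FanGeometry) -> None:
    if image.values.shape != (geometry.image_side, geometry.image_side):
        raise ContractError(
            f"image shape {image.values.shape} does not match geometry "
            f"side {geometry.image_side}"
        )


def forward_project(image: Image, geometry: FanGeometry) -> FanSinogram:
    """Fan-beam forward projection of an attenuation image."""
    _check_image(image, geometry)
    flat = image.values.ravel()
    nbins = geometry.n_detector_bins
    if uses_matrix(geometry):
        sino = (fp_matrix(geometry) @ flat).reshape(geometry.n_views_full, nbins)
    else:
        sino = np.empty((geometry.n_views_full, nbins))
        for i, beta in enumerate(geometry.view_angles):
            bins, cols, wts = _view_splat(geometry, beta)
            sino[i] = np.bincount(bins, weights=wts * flat[cols], minlength=nbins)
    return FanSinogram(sino, geometry)


def forward_project_batch(images: np.ndarray, geometry: FanGeometry) -> np.ndarray:
    """Forward projection of a stack ``(B, N, N)`` -> ``(B, M, n_bins)``."""
    if uses_matrix(geometry):
        a = fp_matrix(geometry)
        b = images.shape[0]
        out = a @ images.reshape(b, -1).T
        return np.ascontiguousarray(out.T).reshape(
            b, geometry.n_views_full, geometry.n_detector_bins
        )
    return np.stack(
        [forward_project(Image(img), geometry).values for img in images]
    )


def true_adjoint(sino: FanSinogram, geometry: FanGeometry) -> Image:
    """Exact transpose of ``forward_project`` (verification mode only)."""
    n = geometry.image_side
    if uses_matrix(geometry):
        cache = _op_cache(geometry)
        if "fpT" not in cache:
            cache["fpT"] = fp_matrix(geometry).T.tocsr()
        return Image((cache["fpT"] @ sino.values.ravel()).reshape(n, n))
    out = np.zeros(n * n)
    for i, beta in enumerate(geometry.view_angles):
        bins, cols, wts = _view_splat(geometry, beta)
        out += np.bincount(
            cols, weights=wts * sino.values[i, bins], minlength=n * n
        )
    return Image(out.reshape(n, n))


def projector_backward(sino_cotangent: FanSinogram, geometry: FanGeometry) -> Image:
    """Training derivative of the forward projection: the FBP operator.

    The unrolled network propagates sinogram-domain loss back to the image
    domain through filtered back-projection rather than the true adjoint.
    """
    from .fbp import fbp_reconstruct

    return fbp_reconstruct(sino_cotangent)
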