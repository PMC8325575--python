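"""Projection data fidelity layer (PDFL).

Given a network-predicted image, its full-grid re-projection ``S_cnn`` is
fused with the acquired limited-view sinogram ``S_u`` row by row: acquired
view ``i`` becomes ``(lam * S_cnn(i) + S_u(i)) / (lam + 1)`` — the
closed-form minimizer of the sinogram data-fidelity term with noise-level
weight ``lam`` — and unacquired views keep the prediction.  The fused
sinogram is then filtered back-projected to the image domain.  With
``lam = 0`` the acquired rows are replaced exactly.

The layer has no learnable parameters.  Its prescribed backward map is
``Gfbp . D . G`` applied to the image cotangent, where ``D`` scales
acquired view rows by ``lam / (1 + lam)`` and leaves the rest untouched.
Acquisition happens per view, so fidelity granularity is a full view row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .fbp import fbp_reconstruct
from .geometry import FanGeometry, Image
from .projector import FanSinogram, forward_project


@dataclass
class ViewMask:
    """The acquired subset of full-scan view indices."""

    acquired: np.ndarray
    n_views_full: int

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.acquired, dtype=np.int64))
        if idx.size == 0:
            raise ContractError("view mask must contain at least one view")
        if idx[0] < 0 or idx[-1] >= self.n_views_full:
            raise ContractError("view indices out of range")
        self.acquired = idx

    def __len__(self) -> int:
        return int(self.acquired.size)

    def indicator(self) -> np.ndarray:
        """Boolean acquired-row indicator of length ``n_views_full``."""
        ind = np.zeros(self.n_views_full, dtype=bool)
        ind[self.acquired] = True
        return ind

    def row_weights(self, lam: float) -> np.ndarray:
        """Diagonal weights e_i: lam/(1+lam) on acquired rows, 1 elsewhere."""
        e = np.ones(self.n_views_full)
        e[self.acquired] = lam / (1.0 + lam)
        return e

    def to_list(self) -> list[int]:
        return [int(i) for i in self.acquired]

    @classmethod
    def from_list(cls, indices, n_views_full: int) -> "ViewMask":
        return cls(np.asarray(list(indices), dtype=np.int64), n_views_full)


@dataclass
class FidelityParams:
    """Noise-level parameter of the sinogram fusion; lam = 0 replaces
    acquired rows exactly."""

    lam: float = 0.001

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ContractError("lam must be non-negative")


def fuse_sinogram(
    s_cnn: FanSinogram,
    s_u: FanSinogram,
    mask: ViewMask,
    params: FidelityParams = FidelityParams(),
) -> FanSinogram:
    """Closed-form row-wise fusion of predicted and acquired sinograms."""
    if s_cnn.values.shape != s_u.values.shape:
        raise ContractError("predicted and acquired sinograms differ in shape")
    if mask.n_views_full != s_cnn.values.shape[0]:
        raise ContractError("mask length does not match sinogram views")
    ind = mask.indicator()
    if np.any(s_u.values[~ind] != 0):
        raise ContractError("acquired sinogram has non-zero rows outside the mask")
    lam = params.lam
    out = s_cnn.values.copy()
    out[ind] = (lam * s_cnn.values[ind] + s_u.values[ind]) / (lam + 1.0)
    return FanSinogram(out, s_cnn.geometry)


def pdfl_forward(
    i_cnn: Image,
    s_u: FanSinogram,
    mask: ViewMask,
    params: FidelityParams = FidelityParams(),
) -> Image:
    """FP -> row fusion -> FBP; an image with projection data fidelity."""
    geometry = s_u.geometry
    s_cnn = forward_project(i_cnn, geometry)
    return fbp_reconstruct(fuse_sinogram(s_cnn, s_u, mask, params))


def pdfl_backward(
    image_cotangent: Image,
    geometry: FanGeometry,
    mask: ViewMask,
    params: FidelityParams = FidelityParams(),
) -> Image:
    """Prescribed backward map Gfbp . D . G applied to an image cotangent."""
    s = forward_project(image_cotangent, geometry)
    scaled = FanSinogram(
        s.values * mask.row_weights(params.lam)[:, None], geometry
    )
    return fbp_reconstruct(scaled)


def sinogram_error_trace(
    cascade_sinograms: list[FanSinogram] | list[np.ndarray],
    s_full: FanSinogram | np.ndarray,
) -> list[float]:
    """Per-cascade-block RMSE against the full-view ground-truth sinogram."""
    if len(cascade_sinograms) == 0:
        raise ContractError("need at least one cascade sinogram")
    ref = s_full.values if isinstance(s_full, FanSinogram) else np.asarray(s_full)
    out = []
    for s in cascade_sinograms:
        v = s.values if isinstance(s, FanSinogram) else np.asarray(s)
        if v.shape != ref.shape:
            raise ContractError("sinogram shapes differ")
        out.append(float(np.sqrt(np.mean((v - ref) ** 2))))
    return out
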