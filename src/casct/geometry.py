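"""Equi-angular fan-beam acquisition geometry and coordinate conventions.

Conventions used by every operator in the package:

* x rightward, y upward, origin at the rotation center.
* The source rotation angle ``beta`` is measured counterclockwise from the
  +y axis, so the source sits at ``(-D sin(beta), D cos(beta))`` where ``D``
  is the source-to-center distance.
* ``gamma`` is the in-fan angle between the central ray (source -> rotation
  center) and a detector ray, positive toward +x at ``beta = 0``.  With
  these signs the fan ray ``(beta, gamma)`` coincides with the parallel ray
  of angle ``alpha = beta + gamma`` and signed offset ``rho = D sin(gamma)``
  in the normal form ``x cos(alpha) + y sin(alpha) = rho``.
* Angles are radians everywhere inside the library; degrees appear only at
  the command line.
* Pixel (row i, col j) of an ``image_side = N`` grid has physical center
  ``x = (j - (N-1)/2) * pixel_size``, ``y = ((N-1)/2 - i) * pixel_size``
  (row 0 at the top).  Odd grids place the middle pixel exactly at the
  rotation center; even grids are symmetric about it with a half-pixel
  offset.  The projector and back-projector share this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

#: Linear attenuation of water at the simulated (monoenergetic) energy,
#: in 1/cm.  Used as the Hounsfield-unit reference.
MU_WATER = 0.2

#: Relative margin added to arcsin(fov/D) so the detector arc covers the
#: whole reconstruction circle.
FAN_MARGIN = 1.02


@dataclass
class FanGeometry:
    """Fan-beam acquisition geometry with an equi-angular arc detector."""

    source_to_center: float          # D, cm
    n_views_full: int                # M
    view_angles: np.ndarray          # beta_i = i * 2*pi/M, radians
    n_detector_bins: int
    fan_half_angle: float            # gamma_max, radians
    detector_gammas: np.ndarray      # equiangular on [-gamma_max, +gamma_max]
    image_side: int                  # N_x = N_y
    pixel_size: float                # cm
    fov_radius: float                # cm

    @property
    def view_spacing(self) -> float:
        """Delta beta = 2*pi / M."""
        return 2.0 * np.pi / self.n_views_full

    @property
    def gamma_spacing(self) -> float:
        if self.n_detector_bins > 1:
            return 2.0 * self.fan_half_angle / (self.n_detector_bins - 1)
        return 2.0 * self.fan_half_angle if self.fan_half_angle > 0 else 1.0

    @property
    def rho_max(self) -> float:
        """Largest parallel-ray offset covered by the fan, cm."""
        return self.source_to_center * np.sin(self.fan_half_angle)

    def validate(self) -> None:
        if self.source_to_center <= 0:
            raise GeometryError("source_to_center must be positive")
        if self.view_angles.shape != (self.n_views_full,):
            raise GeometryError("view_angles length must equal n_views_full")
        if self.n_views_full > 1:
            d = np.diff(self.view_angles)
            if np.any(d <= 0) or not np.allclose(d, self.view_spacing):
                raise GeometryError("view angles must be uniform and increasing")
        if self.detector_gammas.shape != (self.n_detector_bins,):
            raise GeometryError("detector_gammas length mismatch")
        if not np.allclose(self.detector_gammas, -self.detector_gammas[::-1]):
            raise GeometryError("detector gamma grid must be symmetric about 0")
        if self.fov_radius > self.source_to_center * np.sin(self.fan_half_angle) + 1e-12:
            raise GeometryError("fov_radius exceeds the fan coverage D*sin(gamma_max)")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        """Scalar description; the angle grids are derived deterministically."""
        return {
            "source_to_center": float(self.source_to_center),
            "n_views": int(self.n_views_full),
            "n_detectors": int(self.n_detector_bins),
            "image_side": int(self.image_side),
            "fov_radius": float(self.fov_radius),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FanGeometry":
        return make_fan_geometry(
            image_side=d["image_side"],
            n_views=d["n_views"],
            n_detectors=d["n_detectors"],
            source_distance=d["source_to_center"],
            fov_radius=d["fov_radius"],
        )


@dataclass
class Image:
    """2D attenuation map on the reconstruction grid (1/cm)."""

    values: np.ndarray
    hu_reference: float = MU_WATER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise GeometryError("image grid must be 2D square")

    def to_hu(self) -> np.ndarray:
        return mu_to_hu(self.values, self.hu_reference)


def mu_to_hu(mu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """Linear attenuation (1/cm) -> Hounsfield units."""
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water) / mu_water


def hu_to_mu(hu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """Hounsfield units -> linear attenuation (1/cm)."""
    return mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def make_fan_geometry(
    image_side: int,
    n_views: int,
    n_detectors: int,
    source_distance: float,
    fov_radius: float,
) -> FanGeometry:
    """Build an equi-angular fan-beam geometry.

    The fan half-angle is ``arcsin(fov_radius / D)`` widened by a 2% margin
    so every point of the reconstruction circle is seen by every view, and
    the pixel size is ``2 * fov_radius / image_side``.
    """
    if image_side < 1 or n_views < 1 or n_detectors < 1:
        raise GeometryError("all counts must be >= 1")
    if fov_radius >= source_distance:
        raise GeometryError(
            f"fov_radius ({fov_radius}) must be smaller than the "
            f"source-to-center distance ({source_distance})"
        )
    gamma_max = float(np.arcsin(fov_radius / source_distance) * FAN_MARGIN)
    if n_detectors > 1:
        gammas = np.linspace(-gamma_max, gamma_max, n_detectors)
    else:
        gammas = np.zeros(1)
    geom = FanGeometry(
        source_to_center=float(source_distance),
        n_views_full=int(n_views),
        view_angles=np.arange(n_views) * (2.0 * np.pi / n_views),
        n_detector_bins=int(n_detectors),
        fan_half_angle=gamma_max,
        detector_gammas=gammas,
        image_side=int(image_side),
        pixel_size=2.0 * float(fov_radius) / int(image_side),
        fov_radius=float(fov_radius),
    )
    geom.validate()
    return geom


def pixel_centers(geometry: FanGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of every pixel center, cm.

    Returns two ``(N, N)`` arrays ``X[i, j]``, ``Y[i, j]`` for row i, col j.
    """
    n = geometry.image_side
    px = geometry.pixel_size
    half = (n - 1) / 2.0
    cols = (np.arange(n) - half) * px
    rows = (half - np.arange(n)) * px
    X, Y = np.meshgrid(cols, rows)
    return X, Y


def source_position(geometry: FanGeometry, beta: float) -> tuple[float, float]:
    """Source location at rotation angle ``beta``."""
    d = geometry.source_to_center
    return (-d * np.sin(beta), d * np.cos(beta))
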