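"""Synthetic phantoms and limited-view acquisition simulation.

Emulates the study protocol end to end without external data: attenuation
phantoms rasterized from analytic ellipses, full-scan fan-beam projection
(360 views over 0-360 degrees by default), Beer-Lambert transmission with
Poisson counting noise from a 2e7-photon incident beam, and view-subset
masks for sparse-view (keep every k-th view, k in {2, 4, 6}) and
limited-angle (first 90/120/150 degrees) acquisitions.

The x-ray source is modelled as monoenergetic with water at 0.2/cm serving
as the Hounsfield reference; noise is applied to transmission counts
before the log (the physically standard pre-log model), and counts are
clamped at 1 before the log to avoid infinities.  The reconstruction
ground truth of a simulated scan is the FBP of the full noiseless
sinogram, not the phantom itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ContractError
from .fbp import fbp_reconstruct
from .geometry import FanGeometry, Image, hu_to_mu, pixel_centers
from .pdfl import ViewMask
from .projector import FanSinogram, forward_project

#: default incident photons per ray
DEFAULT_PHOTONS = 2.0e7

#: rasterization supersampling factor (antialiased ellipse edges)
_SUPERSAMPLE = 4

# Shepp-Logan-style ellipse table on the unit disk:
# (cx, cy, a, b, angle_deg, relative attenuation)
_SHEPP_LOGAN = [
    (0.0, 0.0, 0.69, 0.92, 0.0, 2.0),
    (0.0, -0.0184, 0.6624, 0.874, 0.0, -0.98),
    (0.22, 0.0, 0.11, 0.31, -18.0, -0.4),
    (-0.22, 0.0, 0.16, 0.41, 18.0, -0.4),
    (0.0, 0.35, 0.21, 0.25, 0.0, 0.2),
    (0.0, 0.1, 0.046, 0.046, 0.0, 0.2),
    (0.0, -0.1, 0.046, 0.046, 0.0, 0.2),
    (-0.08, -0.605, 0.046, 0.023, 0.0, 0.2),
    (0.0, -0.605, 0.023, 0.023, 0.0, 0.2),
    (0.06, -0.605, 0.023, 0.046, 0.0, 0.2),
]


@dataclass
class AcquisitionProtocol:
    """View-sampling and noise settings of a simulated scan."""

    mode: str = "full"               # full | sparse_view | limited_angle
    sv_factor: int = 4               # keep every k-th view
    la_degrees: int = 120            # acquired angular window, degrees
    photons: float | None = DEFAULT_PHOTONS  # None -> noiseless

    def __post_init__(self) -> None:
        if self.mode not in ("full", "sparse_view", "limited_angle"):
            raise ContractError(f"unknown acquisition mode {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "sv_factor": int(self.sv_factor),
            "la_degrees": int(self.la_degrees),
            "photons": None if self.photons is None else float(self.photons),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**d)


@dataclass
class PhantomSpec:
    """Recipe for a synthetic attenuation phantom."""

    kind: str = "random_ellipses"    # random_ellipses | shepp_logan_like
    n_ellipses: tuple[int, int] = (3, 7)
    hu_range: tuple[float, float] = (-800.0, 1200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_ellipses", "shepp_logan_like"):
            raise ContractError(f"unknown phantom kind {self.kind!r}")


def ellipse_attenuation(
    x: np.ndarray, y: np.ndarray, ellipses
) -> np.ndarray:
    """Analytic sum of ellipse attenuations at physical points (x, y).

    ``ellipses`` is an iterable of (cx, cy, a, b, angle_rad, mu).
    """
    out = np.zeros(np.broadcast(x, y).shape)
    for cx, cy, a, b, ang, mu in ellipses:
        ca, sa = np.cos(ang), np.sin(ang)
        xr = (x - cx) * ca + (y - cy) * sa
        yr = -(x - cx) * sa + (y - cy) * ca
        out += np.where((xr / a) ** 2 + (yr / b) ** 2 <= 1.0, mu, 0.0)
    return out


def rasterize_ellipses(geometry: FanGeometry, ellipses) -> Image:
    """Supersampled rasterization of an analytic ellipse phantom."""
    n = geometry.image_side
    s = _SUPERSAMPLE
    px = geometry.pixel_size / s
    half = (n * s - 1) / 2.0
    coords = (np.arange(n * s) - half) * px
    X, Y = np.meshgrid(coords, -coords)  # row 0 at top, y decreasing with row
    fine = ellipse_attenuation(X, Y, ellipses)
    vals = fine.reshape(n, s, n, s).mean(axis=(1, 3))
    return Image(vals)


def _random_ellipses(spec: PhantomSpec, geometry: FanGeometry):
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.n_ellipses
    k = int(rng.integers(lo, hi + 1))
    fov = geometry.fov_radius
    ells = []
    # a soft-tissue-like background disk keeps the support inside the FOV
    bg_hu = rng.uniform(-100.0, 100.0)
    ells.append((0.0, 0.0, 0.9 * fov, 0.9 * fov, 0.0, hu_to_mu(bg_hu) - hu_to_mu(-1000.0)))
    for _ in range(k):
        a = rng.uniform(0.05, 0.35) * fov
        b = rng.uniform(0.05, 0.35) * fov
        rmax = 0.9 * fov - max(a, b)
        rad = rng.uniform(0.0, max(rmax, 0.0))
        th = rng.uniform(0.0, 2 * np.pi)
        hu = rng.uniform(*spec.hu_range)
        # contrast relative to the background, as attenuation increment
        dmu = hu_to_mu(hu) - hu_to_mu(0.0)
        ells.append((rad * np.cos(th), rad * np.sin(th), a, b,
                     rng.uniform(0, np.pi), dmu))
    return ells


def _shepp_logan_ellipses(geometry: FanGeometry):
    scale = 0.95 * geometry.fov_radius
    mu_unit = hu_to_mu(0.0) / 2.0  # relative value 2.0 -> water-like interior
    return [
        (cx * scale, cy * scale, a * scale, b * scale, np.deg2rad(ang), rel * mu_unit)
        for cx, cy, a, b, ang, rel in _SHEPP_LOGAN
    ]


def make_phantom(spec: PhantomSpec, geometry: FanGeometry) -> Image:
    """Deterministic attenuation phantom for a given spec and geometry."""
    if spec.kind == "shepp_logan_like":
        ells = _shepp_logan_ellipses(geometry)
    else:
        ells = _random_ellipses(spec, geometry)
    img = rasterize_ellipses(geometry, ells)
    img.values = np.maximum(img.values, 0.0)
    return img


def sample_views(protocol: AcquisitionProtocol, geometry: FanGeometry) -> ViewMask:
    """View subset of the full scan implied by the acquisition protocol."""
    m = geometry.n_views_full
    if protocol.mode == "full":
        return ViewMask(np.arange(m), m)
    if protocol.mode == "sparse_view":
        if m % protocol.sv_factor:
            raise ContractError(
                f"full view count {m} not divisible by sparse factor "
                f"{protocol.sv_factor}"
            )
        return ViewMask(np.arange(0, m, protocol.sv_factor), m)
    # limited angle: views with beta in [0, la_degrees)
    lim = np.deg2rad(protocol.la_degrees)
    idx = np.nonzero(geometry.view_angles < lim - 1e-12)[0]
    return ViewMask(idx, m)


def simulate_acquisition(
    image: Image,
    protocol: AcquisitionProtocol,
    geometry: FanGeometry,
    seed: int = 0,
) -> tuple[FanSinogram, Image]:
    """Project, add counting noise on acquired views, reconstruct naively.

    Returns the zero-filled limited-view sinogram ``s_u`` and its plain FBP
    reconstruction ``i_u``.
    """
    mask = sample_views(protocol, geometry)
    s = forward_project(image, geometry)
    vals = np.zeros_like(s.values)
    ind = mask.indicator()
    if protocol.photons is None:
        vals[ind] = s.values[ind]
    else:
        rng = np.random.default_rng(seed)
        i0 = float(protocol.photons)
        counts = rng.poisson(i0 * np.exp(-s.values[ind]))
        vals[ind] = -np.log(np.maximum(counts, 1) / i0)
    s_u = FanSinogram(vals, geometry)
    return s_u, fbp_reconstruct(s_u)


@dataclass
class Sample:
    """One training/evaluation item of the simulated dataset."""

    i_u: Image
    s_u: FanSinogram
    mask: ViewMask
    i_gt: Image
    phantom: Image


def make_samples(
    n: int,
    protocol: AcquisitionProtocol,
    geometry: FanGeometry,
    seed: int,
    phantom_kind: str = "random_ellipses",
) -> list[Sample]:
    """Generate ``n`` independent simulated scans (deterministic in seed)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    out = []
    for child in children:
        s1, s2 = child.generate_state(2) % (2**31)
        spec = PhantomSpec(kind=phantom_kind, seed=int(s1))
        phantom = make_phantom(spec, geometry)
        s_full = forward_project(phantom, geometry)
        i_gt = fbp_reconstruct(s_full)
        s_u, i_u = simulate_acquisition(phantom, protocol, geometry, seed=int(s2))
        out.append(Sample(i_u, s_u, sample_views(protocol, geometry), i_gt, phantom))
    return out


def build_dataset(
    path,
    n_train: int,
    n_val: int,
    n_test: int,
    protocol: AcquisitionProtocol,
    geometry: FanGeometry,
    seed: int = 0,
    phantom_kind: str = "random_ellipses",
) -> None:
    """Write an HDF5 dataset of (i_u, s_u, mask, i_gt) items with a manifest."""
    if min(n_train, n_val, n_test) < 0:
        raise ContractError("split sizes must be non-negative")
    splits = {"train": n_train, "val": n_val, "test": n_test}
    ss = np.random.SeedSequence(seed)
    split_seeds = {k: int(s.generate_state(1)[0] % (2**31))
                   for k, s in zip(splits, ss.spawn(len(splits)))}
    manifest = {"splits": {}, "protocol": protocol.to_dict(),
                "geometry": geometry.to_dict(), "seed": int(seed)}
    with h5py.File(path, "w") as f:
        for key, val in geometry.to_dict().items():
            f.attrs[f"geometry_{key}"] = val
        items = f.create_group("items")
        counter = 0
        for split, n in splits.items():
            samples = make_samples(n, protocol, geometry, split_seeds[split],
                                   phantom_kind)
            ids = []
            for s in samples:
                gid = f"{counter:05d}"
                grp = items.create_group(gid)
                grp.create_dataset("i_u", data=s.i_u.values)
                grp.create_dataset("s_u", data=s.s_u.values)
                grp.create_dataset("mask", data=s.mask.acquired)
                grp.create_dataset("i_gt", data=s.i_gt.values)
                grp.create_dataset("phantom", data=s.phantom.values)
                grp.attrs["split"] = split
                ids.append(gid)
                counter += 1
            manifest["splits"][split] = ids
        f.attrs["manifest"] = json.dumps(manifest)


def load_dataset(path, split: str | None = None) -> list[Sample]:
    """Read items (optionally one split) back from an HDF5 dataset file."""
    out = []
    with h5py.File(path, "r") as f:
        geometry = FanGeometry.from_dict(
            {k[len("geometry_"):]: v for k, v in f.attrs.items()
             if k.startswith("geometry_")}
        )
        for gid in sorted(f["items"]):
            grp = f["items"][gid]
            if split is not None and grp.attrs["split"] != split:
                continue
            mask = ViewMask(grp["mask"][...], geometry.n_views_full)
            out.append(
                Sample(
                    Image(grp["i_u"][...]),
                    FanSinogram(grp["s_u"][...], geometry),
                    mask,
                    Image(grp["i_gt"][...]),
                    Image(grp["phantom"][...]),
                )
            )
    return out
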