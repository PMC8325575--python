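"""File formats: HDF5 sinograms, NPY/TIFF images, YAML run configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .cascade import CascadeConfig, TrainConfig
from .errors import ContractError
from .geometry import FanGeometry, Image
from .pdfl import FidelityParams, ViewMask
from .projector import FanSinogram
from .redscan import RedSCANConfig
from .simulate import AcquisitionProtocol


def save_sinogram(path, sino: FanSinogram, mask: ViewMask | None = None) -> None:
    """Write a sinogram with its geometry (and optional view mask) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("sinogram", data=sino.values)
        for k, v in sino.geometry.to_dict().items():
            f.attrs[f"geometry_{k}"] = v
        if mask is not None:
            f.attrs["view_mask"] = json.dumps(mask.to_list())


def load_sinogram(path) -> tuple[FanSinogram, ViewMask | None]:
    with h5py.File(path, "r") as f:
        geom = FanGeometry.from_dict(
            {k[len("geometry_"):]: v for k, v in f.attrs.items()
             if k.startswith("geometry_")}
        )
        sino = FanSinogram(f["sinogram"][...], geom)
        mask = None
        if "view_mask" in f.attrs:
            mask = ViewMask.from_list(
                json.loads(f.attrs["view_mask"]), geom.n_views_full
            )
    return sino, mask


def load_image(path) -> np.ndarray:
    """Read a 2D image array from .npy or TIFF."""
    p = Path(path)
    if p.suffix == ".npy":
        return np.load(p)
    if p.suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(p), dtype=float)
    raise ContractError(f"unsupported image format: {p.suffix}")


def save_image(path, values: np.ndarray) -> None:
    p = Path(path)
    if p.suffix == ".npy":
        np.save(p, values)
    elif p.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(p, np.asarray(values, np.float32))
    else:
        raise ContractError(f"unsupported image format: {p.suffix}")


# ---------------------------------------------------------------------------
# YAML run configs

def config_to_yaml(
    geometry: FanGeometry,
    protocol: AcquisitionProtocol | None = None,
    cascade: CascadeConfig | None = None,
    train: TrainConfig | None = None,
) -> str:
    doc: dict = {"geometry": geometry.to_dict()}
    if protocol is not None:
        doc["protocol"] = protocol.to_dict()
    if cascade is not None:
        doc["cascade"] = asdict(cascade)
    if train is not None:
        doc["train"] = asdict(train)
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> dict:
    """Parse a run config; returns dataclass instances keyed by section."""
    doc = yaml.safe_load(text)
    out: dict = {"geometry": FanGeometry.from_dict(doc["geometry"])}
    if "protocol" in doc:
        out["protocol"] = AcquisitionProtocol.from_dict(doc["protocol"])
    if "cascade" in doc:
        c = dict(doc["cascade"])
        c["fidelity"] = FidelityParams(**c["fidelity"])
        c["backbone"] = RedSCANConfig(**c["backbone"])
        c["hu_window"] = tuple(c["hu_window"])
        out["cascade"] = CascadeConfig(**c)
    if "train" in doc:
        out["train"] = TrainConfig(**doc["train"])
    return out


def write_config(path, **sections) -> None:
    Path(path).write_text(config_to_yaml(**sections))


def read_config(path) -> dict:
    return config_from_yaml(Path(path).read_text())
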