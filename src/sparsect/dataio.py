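"""Image, sinogram and checkpoint I/O.

Images: lossless HDF5 datasets with provenance attributes, plus 16-bit
TIFF/PNG exports (affinely scaled to the integer range, scale recorded in
the metadata where the format allows).  Sinograms: HDF5 with the full scan
geometry stored as attributes.  JSON sidecars carry run provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .projector import ScanGeometry, Sinogram

__all__ = ["save_image_h5", "load_image_h5", "save_image_tiff",
           "save_image_png", "load_image_any", "save_sinogram",
           "load_sinogram", "write_json", "read_json"]


def save_image_h5(path, img: np.ndarray, **attrs) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("image", data=np.asarray(img, np.float64))
        for k, v in attrs.items():
            d.attrs[k] = v


def load_image_h5(path) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        d = f["image"]
        return d[()], dict(d.attrs)


def save_image_tiff(path, img: np.ndarray) -> None:
    """16-bit TIFF, affinely scaled from the image's own range."""
    img = np.asarray(img, float)
    lo, hi = float(img.min()), float(img.max())
    scale = (hi - lo) or 1.0
    data = np.round((img - lo) / scale * 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"min": lo, "max": hi})


def save_image_png(path, img: np.ndarray) -> None:
    img = np.asarray(img, float)
    lo, hi = float(img.min()), float(img.max())
    scale = (hi - lo) or 1.0
    data = np.round((img - lo) / scale * 65535).astype(np.uint16)
    iio.imwrite(path, data)


def load_image_any(path) -> np.ndarray:
    """Load a ground-truth image from TIFF/PNG (rescaled to [0, 1]) or an
    HDF5 file (stored values, assumed already in [0, 1])."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        img, _ = load_image_h5(path)
        return np.asarray(img, float)
    img = np.asarray(iio.imread(path), float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    lo, hi = img.min(), img.max()
    return (img - lo) / ((hi - lo) or 1.0)


def save_sinogram(path, sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sinogram", data=sino.values)
        for field in dataclasses.fields(ScanGeometry):
            d.attrs[field.name] = getattr(sino.geometry, field.name)
        d.attrs["noise_level"] = sino.noise_level
        d.attrs["seed"] = -1 if sino.seed is None else sino.seed


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        d = f["sinogram"]
        a = dict(d.attrs)
        geom = ScanGeometry(
            beam=str(a["beam"]), angle_start=float(a["angle_start"]),
            angle_end=float(a["angle_end"]), n_views=int(a["n_views"]),
            n_detectors=int(a["n_detectors"]),
            detector_spacing=float(a["detector_spacing"]),
            source_axis_distance=float(a["source_axis_distance"]),
            axis_detector_distance=float(a["axis_detector_distance"]),
            protocol_tag=str(a["protocol_tag"]))
        seed = int(a["seed"])
        return Sinogram(d[()], geom, float(a["noise_level"]),
                        None if seed < 0 else seed)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
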