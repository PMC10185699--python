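"""File round-trips for pipeline artifacts: NIfTI volumes and masks, YAML
specs, PNG/NumPy MIPs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .mip import MIPImage
from .phantom import CohortSpec, PhantomSpec

__all__ = [
    "save_nifti", "load_nifti", "save_mask", "load_mask",
    "save_mip", "load_mip", "spec_to_yaml", "spec_from_yaml",
]


def save_nifti(volume: np.ndarray, spacing_mm, path) -> None:
    """Write a volume as NIfTI with voxel spacing on the affine diagonal."""
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=np.float32), spacing


def save_mask(mask: np.ndarray, spacing_mm, path) -> None:
    save_nifti(mask.astype(np.uint8), spacing_mm, path)


def load_mask(path) -> np.ndarray:
    data, _ = load_nifti(path)
    return data > 0.5


def save_mip(mip: MIPImage, stem: Path) -> None:
    """Write ``<stem>.mip.npy`` (lossless model input) and ``<stem>.mip.png``."""
    np.save(f"{stem}.mip.npy", mip.pixels)
    from PIL import Image

    Image.fromarray((mip.pixels * 255).astype(np.uint8)).save(f"{stem}.mip.png")


def load_mip(path, suv_cap: float) -> MIPImage:
    return MIPImage(pixels=np.load(path), suv_cap=suv_cap)


_SPEC_TYPES = {"phantom": PhantomSpec, "cohort": CohortSpec}


def spec_to_yaml(spec, path) -> None:
    kind = "phantom" if isinstance(spec, PhantomSpec) else "cohort"
    payload = {"kind": kind, **dataclasses.asdict(spec)}
    for key, value in payload.items():
        if isinstance(value, tuple):
            payload[key] = list(value)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def spec_from_yaml(path):
    payload = yaml.safe_load(Path(path).read_text())
    cls = _SPEC_TYPES[payload.pop("kind")]
    fields = {f.name: f.type for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in fields:
            raise ValueError(f"unknown field {key!r} for {cls.__name__}")
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)
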