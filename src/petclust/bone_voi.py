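"""Skeletal volume-of-interest from CT by HU thresholding.

The VOI is the set of voxels with CT attenuation strictly above a threshold
(default 150 HU), followed by automated removal of small connected
components (26-connectivity) standing in for manual cleanup of non-skeletal
high-attenuation structures.  PET volumes restricted to the VOI mark
excluded voxels with NaN so that an SUV of exactly 0 inside bone remains
distinguishable from "outside the VOI".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["BoneMask", "extract_bone_mask", "apply_mask"]

EXCLUDED = np.nan
"""Sentinel value carried by out-of-mask voxels after :func:`apply_mask`."""


@dataclass(frozen=True)
class BoneMask:
    """Binary skeletal mask congruent with its source CT grid."""

    mask: np.ndarray
    hu_threshold: float
    min_component_voxels: int

    def __post_init__(self):
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def provenance(self) -> str:
        return (
            f"HU > {self.hu_threshold}; connected components < "
            f"{self.min_component_voxels} voxels removed (26-connectivity)"
        )


def extract_bone_mask(
    ct: np.ndarray,
    hu_threshold: float = 150.0,
    min_component_voxels: int = 20,
) -> BoneMask:
    """Threshold CT at ``hu_threshold`` (strict ``>``) and drop small components.

    Parameters
    ----------
    ct
        CT volume in Hounsfield units; must be finite.
    hu_threshold
        Voxels with HU strictly above this value enter the mask.
    min_component_voxels
        Connected components (26-connectivity) smaller than this are
        removed — an automated proxy for manual exclusion of calcifications
        and foreign material.

    Raises
    ------
    ValueError
        If the CT contains non-finite values or the cleaned mask is empty.
    """
    ct = np.asarray(ct)
    if not np.all(np.isfinite(ct)):
        raise ValueError("CT volume contains non-finite values")
    raw = ct > hu_threshold
    mask = raw
    if min_component_voxels > 1 and raw.any():
        structure = np.ones((3,) * ct.ndim, dtype=bool)  # 26-connectivity in 3-D
        labels, n = ndimage.label(raw, structure=structure)
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_component_voxels
            keep[0] = False
            mask = keep[labels]
    if not mask.any():
        raise ValueError(
            f"empty bone mask: no connected component of >= {min_component_voxels} "
            f"voxels exceeds {hu_threshold} HU"
        )
    return BoneMask(mask=mask, hu_threshold=float(hu_threshold),
                    min_component_voxels=int(min_component_voxels))


def apply_mask(pet: np.ndarray, mask: BoneMask) -> np.ndarray:
    """Restrict a PET volume to the bone VOI.

    Returns a float volume in which in-mask voxels keep their SUV unchanged
    and out-of-mask voxels carry NaN (:data:`EXCLUDED`), so they can never
    be confused with a genuine SUV of 0 inside bone.
    """
    pet = np.asarray(pet, dtype=float)
    m = mask.mask
    if pet.shape != m.shape:
        raise ValueError(
            f"PET shape {pet.shape} does not match mask shape {m.shape}"
        )
    out = np.where(m, pet, EXCLUDED)
    return out
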