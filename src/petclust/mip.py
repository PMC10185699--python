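"""Normalized anterior maximum-intensity projections.

Each masked SUV volume is projected along the anterior-posterior axis
(voxelwise maximum, excluded voxels treated as 0), cropped to the bounding
box of nonzero pixels, resized to a fixed 64-pixel-wide by 128-pixel-tall
image (bilinear, aspect ratio not preserved), and mapped to [0, 1] by
dividing by a fixed SUV cap with clipping.  A fixed cap — rather than
per-image max scaling — keeps between-subject intensity differences, which
is what separates high-burden from low-burden subjects downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = ["MIPImage", "make_mip", "MIP_WIDTH", "MIP_HEIGHT"]

MIP_WIDTH = 64
MIP_HEIGHT = 128


@dataclass(frozen=True)
class MIPImage:
    """64 x 128 (width x height) normalized projection in [0, 1].

    ``pixels`` is stored as ``(height, width) = (128, 64)``, rows running
    superior to inferior.
    """

    pixels: np.ndarray
    suv_cap: float

    def __post_init__(self):
        if self.pixels.shape != (MIP_HEIGHT, MIP_WIDTH):
            raise ValueError(
                f"MIP must be {MIP_HEIGHT}x{MIP_WIDTH} (height x width), "
                f"got {self.pixels.shape}"
            )
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("MIP pixels must lie in [0, 1]")


def make_mip(masked_suv: np.ndarray, suv_cap: float = 10.0, crop: bool = True) -> MIPImage:
    """Project a masked SUV volume to a normalized anterior MIP.

    Parameters
    ----------
    masked_suv
        ``(x, y, z)`` volume from :func:`petclust.bone_voi.apply_mask`;
        NaN marks out-of-VOI voxels and projects as 0.
    suv_cap
        SUV mapped to pixel value 1.0; higher uptake clips.
    crop
        Crop to the bounding box of nonzero projected pixels before
        resizing (default).  With ``crop=False`` the full projection is
        resized.
    """
    if suv_cap <= 0:
        raise ValueError("suv_cap must be positive")
    vol = np.asarray(masked_suv, dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {vol.shape}")
    proj = np.nanmax(np.nan_to_num(vol, nan=0.0), axis=1)  # max over anterior-posterior
    if not (proj > 0).any():
        raise ValueError("nothing to project: all-zero anterior projection")
    # rows superior -> inferior, columns left -> right
    img = proj.T[::-1, :]
    if crop:
        rows = np.flatnonzero((img > 0).any(axis=1))
        cols = np.flatnonzero((img > 0).any(axis=0))
        img = img[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    img = resize(
        img, (MIP_HEIGHT, MIP_WIDTH), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    img = np.clip(img / suv_cap, 0.0, 1.0)
    return MIPImage(pixels=img, suv_cap=float(suv_cap))
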