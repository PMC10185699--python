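"""Conventional PET burden metrics inside the skeletal VOI.

SUV converts an activity-concentration image to standardized uptake values
(activity x body weight / injected dose).  Within a bone mask the module
reports SUVmax and SUVmean over the whole VOI, metabolic tumor volume (MTV)
as the volume of in-mask voxels with SUV at or above a threshold (default
2.5, inclusive), and total lesion glycolysis (TLG) as MTV times the mean
SUV of those supra-threshold voxels.  The VOI-wide mean and the
supra-threshold mean are reported as distinct quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bone_voi import BoneMask

__all__ = ["ConventionalParams", "compute_suv", "conventional_params"]


@dataclass(frozen=True)
class ConventionalParams:
    """SUVmax / SUVmean / MTV / TLG for one subject.

    ``suv_mean_voi`` averages over the entire VOI; ``suv_mean_lesion``
    averages over the supra-threshold (MTV) voxels only and is the mean
    entering TLG.  ``suv_mean_lesion`` is 0 when MTV is 0.
    """

    suv_max: float
    suv_mean_voi: float
    suv_mean_lesion: float
    mtv_cm3: float
    tlg: float
    suv_threshold: float

    def as_dict(self) -> dict[str, float]:
        return {
            "suv_max": self.suv_max,
            "suv_mean_voi": self.suv_mean_voi,
            "suv_mean_lesion": self.suv_mean_lesion,
            "mtv_cm3": self.mtv_cm3,
            "tlg": self.tlg,
        }


def compute_suv(activity_bq_ml: np.ndarray, injected_dose_bq: float,
                body_weight_g: float) -> np.ndarray:
    """Voxelwise SUV = activity [Bq/mL] x body weight [g] / injected dose [Bq].

    With tissue density ~1 g/mL this is the standard body-weight SUV and is
    unitless.
    """
    if injected_dose_bq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_bq}")
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_g}")
    return np.asarray(activity_bq_ml, dtype=float) * (body_weight_g / injected_dose_bq)


def conventional_params(
    suv: np.ndarray,
    mask: BoneMask | np.ndarray,
    voxel_volume_cm3: float,
    suv_threshold: float = 2.5,
) -> ConventionalParams:
    """Compute SUVmax, SUVmean, MTV and TLG over a bone VOI.

    MTV counts in-mask voxels with ``SUV >= suv_threshold`` (inclusive)
    times the voxel volume; TLG multiplies MTV by the mean SUV of exactly
    those voxels.  Both are 0 when no voxel reaches the threshold.
    """
    m = mask.mask if isinstance(mask, BoneMask) else np.asarray(mask, dtype=bool)
    suv = np.asarray(suv, dtype=float)
    if suv.shape != m.shape:
        raise ValueError(f"SUV shape {suv.shape} does not match mask shape {m.shape}")
    if not m.any():
        raise ValueError("empty bone mask")
    if voxel_volume_cm3 <= 0:
        raise ValueError("voxel volume must be positive")
    vals = suv[m]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite SUV inside the VOI")
    supra = vals[vals >= suv_threshold]
    mtv = float(len(supra)) * voxel_volume_cm3
    mean_lesion = float(supra.mean()) if len(supra) else 0.0
    return ConventionalParams(
        suv_max=float(vals.max()),
        suv_mean_voi=float(vals.mean()),
        suv_mean_lesion=mean_lesion,
        mtv_cm3=mtv,
        tlg=mtv * mean_lesion,
        suv_threshold=float(suv_threshold),
    )
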