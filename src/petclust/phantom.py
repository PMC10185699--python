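"""Synthetic whole-body PET/CT phantoms and survival cohorts.

The phantom is a stylized axial skeleton (vertebral column, skull, pelvis,
rib arcs, proximal femora) built from unions of simple solids on a regular
voxel grid.  It carries the two contrasts the downstream pipeline actually
uses: a high-Hounsfield-unit skeleton against soft tissue on CT, and focal
skeletal lesions of controllable total volume and SUV against a low-uptake
bone background on PET.  Cohorts pair one phantom per subject with clinical
covariates and a progression-free-survival time drawn from a proportional-
hazards model whose hazard increases with the planted lesion burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VolumePair",
    "PhantomSpec",
    "CohortSpec",
    "PhantomResult",
    "Cohort",
    "generate_phantom",
    "simulate_cohort",
]


@dataclass(frozen=True)
class VolumePair:
    """Co-registered CT (Hounsfield units) and PET (SUV) grids.

    Axis convention: ``(x, y, z)`` = (left-right, anterior-posterior,
    inferior-superior); index ``z`` increases toward the head.
    """

    ct: np.ndarray
    suv: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        if self.ct.shape != self.suv.shape:
            raise ValueError(
                f"CT shape {self.ct.shape} and PET shape {self.suv.shape} differ"
            )

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.voxel_spacing_mm
        return float(sx * sy * sz) / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic subject volume.

    ``lesion_volume_cm3`` is the *total* target volume over all lesions; the
    generator plants it exactly to the nearest whole voxel.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 160)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    bone_hu: float = 400.0
    soft_tissue_hu: float = 40.0
    lesion_count: int = 3
    lesion_volume_cm3: float = 30.0
    lesion_suv: float = 5.0
    background_bone_suv: float = 1.0
    soft_tissue_suv: float = 0.5
    n_distractors: int = 0
    distractor_hu: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.bone_hu <= 150:
            raise ValueError(f"bone_hu must exceed 150 HU, got {self.bone_hu}")
        if self.lesion_suv < 0:
            raise ValueError("lesion_suv must be >= 0")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        if self.lesion_volume_cm3 < 0:
            raise ValueError("lesion_volume_cm3 must be >= 0")
        if self.lesion_count == 0 and self.lesion_volume_cm3 > 0:
            raise ValueError("lesion_volume_cm3 > 0 requires lesion_count >= 1")


@dataclass(frozen=True)
class PhantomResult:
    """A generated phantom with its ground truth."""

    volumes: VolumePair
    lesion_mask: np.ndarray
    skeleton_mask: np.ndarray
    spec: PhantomSpec

    @property
    def true_mtv_cm3(self) -> float:
        return float(self.lesion_mask.sum()) * self.volumes.voxel_volume_cm3


def _skeleton_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Stylized axial skeleton as a boolean grid.

    Proportions are defined on a canonical 64 x 64 x 160 grid and scaled to
    ``shape``.  Only HU contrast and lesion placement matter downstream, so
    the geometry is deliberately schematic.
    """
    nx, ny, nz = shape
    sx, sy, sz = nx / 64.0, ny / 64.0, nz / 160.0
    x, y, z = np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    mask = np.zeros(shape, dtype=bool)

    # vertebral column + sacrum
    spine = ((x - cx) ** 2 + (y - (cy + 2 * sy)) ** 2 <= (4.5 * sx) ** 2) & (
        z >= 30 * sz
    ) & (z <= 132 * sz)
    mask |= spine

    # skull: ellipsoidal shell (cranial vault)
    r2 = (
        ((x - cx) / (11 * sx)) ** 2
        + ((y - cy) / (12 * sy)) ** 2
        + ((z - 145 * sz) / (12 * sz)) ** 2
    )
    mask |= (r2 <= 1.0) & (r2 >= 0.5)

    # pelvis: two iliac blobs flanking the sacrum
    for side in (-1.0, 1.0):
        r2 = (
            ((x - (cx + side * 9 * sx)) / (7 * sx)) ** 2
            + ((y - cy) / (9 * sy)) ** 2
            + ((z - 42 * sz) / (10 * sz)) ** 2
        )
        mask |= r2 <= 1.0

    # proximal femora
    for side in (-1.0, 1.0):
        fem = (
            ((x - (cx + side * 10 * sx)) ** 2 + (y - cy) ** 2 <= (3.5 * sx) ** 2)
            & (z >= 2 * sz)
            & (z <= 36 * sz)
        )
        mask |= fem

    # rib arcs: elliptical rings at thoracic levels
    ring = ((x - cx) / (20 * sx)) ** 2 + ((y - cy) / (13 * sy)) ** 2
    for zc in (82, 92, 102, 112, 122):
        mask |= (ring <= 1.0) & (ring >= 0.72) & (np.abs(z - zc * sz) <= 1.5 * sz)

    return mask


def _plant_lesions(
    skeleton: np.ndarray,
    n_lesions: int,
    n_voxels: int,
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow ``n_lesions`` blobs inside the skeleton totalling ``n_voxels``.

    Each lesion grows outward from a random bone seed voxel by taking the
    nearest still-available bone voxels, so the planted voxel count is exact.
    """
    lesion = np.zeros(skeleton.shape, dtype=bool)
    if n_voxels == 0 or n_lesions == 0:
        return lesion
    coords = np.argwhere(skeleton)
    if n_voxels > len(coords):
        deficit = n_voxels - len(coords)
        raise ValueError(
            f"requested lesion volume needs {n_voxels} skeletal voxels but only "
            f"{len(coords)} are available (deficit {deficit} voxels)"
        )
    coords_mm = coords * np.asarray(spacing, dtype=float)
    quota = np.full(n_lesions, n_voxels // n_lesions, dtype=int)
    quota[: n_voxels % n_lesions] += 1
    available = np.ones(len(coords), dtype=bool)
    centers = rng.choice(len(coords), size=n_lesions, replace=False)
    for c_idx, q in zip(centers, quota):
        if q == 0:
            continue
        d2 = ((coords_mm - coords_mm[c_idx]) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")
        take = order[available[order]][:q]
        available[take] = False
        sel = coords[take]
        lesion[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return lesion


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build one CT/PET phantom with ground-truth skeleton and lesion masks.

    The CT is ``soft_tissue_hu`` everywhere except the skeleton
    (``bone_hu``) and any distractor foci; the PET is ``soft_tissue_suv``
    outside bone, ``background_bone_suv`` in non-lesion bone and
    ``lesion_suv`` in lesion voxels.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    skeleton = _skeleton_mask(spec.grid_shape)
    voxel_volume = float(np.prod(spec.voxel_spacing_mm)) / 1000.0
    n_voxels = int(round(spec.lesion_volume_cm3 / voxel_volume))
    lesion = _plant_lesions(
        skeleton, spec.lesion_count if n_voxels else 0, n_voxels,
        spec.voxel_spacing_mm, rng,
    )

    ct = np.full(spec.grid_shape, spec.soft_tissue_hu, dtype=np.float32)
    ct[skeleton] = spec.bone_hu

    if spec.n_distractors:
        # small high-HU foci outside the skeleton (e.g. vascular
        # calcification), kept clear of the skeleton so they stay separate
        # connected components
        from scipy import ndimage

        near_bone = ndimage.binary_dilation(skeleton, np.ones((3, 3, 3), bool))
        nonbone = np.argwhere(~near_bone)
        picks = rng.choice(len(nonbone), size=spec.n_distractors, replace=False)
        for p in picks:
            i, j, k = nonbone[p]
            ct[i, j, k] = spec.distractor_hu

    suv = np.full(spec.grid_shape, spec.soft_tissue_suv, dtype=np.float32)
    suv[skeleton] = spec.background_bone_suv
    suv[lesion] = spec.lesion_suv

    volumes = VolumePair(ct=ct, suv=suv, voxel_spacing_mm=spec.voxel_spacing_mm)
    return PhantomResult(volumes=volumes, lesion_mask=lesion, skeleton_mask=skeleton, spec=spec)


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a phantom cohort with survival endpoints.

    Lesion burden is a zero-inflated lognormal: a point mass ``p_zero`` at
    no focal disease, otherwise ``exp(N(log_volume_mu, log_volume_sigma))``
    cm3.  Alternatively ``burden_levels``/``burden_level_probs`` draw the
    burden from a discrete set of levels, which is useful for cohorts with
    planted burden tiers.  Event times are exponential given the linear predictor
    ``beta_burden * log(1 + V_true) + beta_asct * ASCT`` (proportional
    hazards by construction); censoring is an independent exponential
    competing time plus an administrative cap.

    Defaults emulate a newly diagnosed multiple myeloma cohort: median
    burden ~33 cm3 with ~14% of subjects free of focal lesions, median age
    62, 54% male, stage mix ~27/52/21%, 53% transplanted, and a protective
    transplant effect (hazard ratio ~0.43).
    """

    n_subjects: int = 60
    p_zero: float = 0.14
    log_volume_mu: float = float(np.log(33.0))
    log_volume_sigma: float = 1.1
    max_volume_cm3: float = 600.0
    burden_levels: tuple[float, ...] | None = None
    burden_level_probs: tuple[float, ...] | None = None
    burden_level_suvs: tuple[float, ...] | None = None
    burden_level_bg_suvs: tuple[float, ...] | None = None
    beta_burden: float = 0.4
    beta_asct: float = -0.85
    baseline_hazard: float = 4e-4
    censor_rate: float = 3e-4
    max_followup_days: float = 3272.0
    age_mean: float = 62.0
    age_sd: float = 10.0
    p_male: float = 0.539
    stage_probs: tuple[float, float, float] = (0.267, 0.524, 0.209)
    p_asct: float = 0.529
    grid_shape: tuple[int, int, int] = (64, 64, 160)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not 0 <= self.p_zero <= 1:
            raise ValueError("p_zero must be in [0, 1]")
        if self.burden_levels is not None:
            probs = self.burden_level_probs
            if probs is None or len(probs) != len(self.burden_levels):
                raise ValueError("burden_level_probs must match burden_levels")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("burden_level_probs must sum to 1")
            for name in ("burden_level_suvs", "burden_level_bg_suvs"):
                vals = getattr(self, name)
                if vals is not None and len(vals) != len(self.burden_levels):
                    raise ValueError(f"{name} must match burden_levels")


@dataclass
class Cohort:
    """Simulated cohort: per-subject records plus phantom specifications.

    ``records`` carries one row per subject (covariates, PFS time, event
    flag, true lesion burden).  ``phantom_specs`` lets volumes be realized
    lazily via :func:`generate_phantom`; ``phantoms`` is populated only when
    the cohort was simulated with ``volumes=True``.
    """

    spec: CohortSpec
    records: pd.DataFrame
    phantom_specs: list[PhantomSpec]
    phantoms: list[PhantomResult] | None = None

    def realize_phantom(self, i: int) -> PhantomResult:
        if self.phantoms is not None:
            return self.phantoms[i]
        return generate_phantom(self.phantom_specs[i])


def simulate_cohort(cohort: CohortSpec, volumes: bool = True) -> Cohort:
    """Draw a reproducible phantom cohort from ``cohort``.

    Set ``volumes=False`` to skip volume generation when only the survival
    records are needed (e.g. statistical calibration at large n); the
    per-subject :class:`PhantomSpec` list still allows exact regeneration.
    """
    if cohort.n_subjects < 2:
        warnings.warn(
            "cohorts with fewer than 2 subjects cannot support downstream "
            "model fitting",
            stacklevel=2,
        )
    ss = np.random.SeedSequence(cohort.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(cohort.n_subjects + 1)[1:]]

    n = cohort.n_subjects
    level_idx = None
    if cohort.burden_levels is not None:
        levels = np.asarray(cohort.burden_levels, dtype=float)
        level_idx = rng.choice(len(levels), size=n, p=cohort.burden_level_probs)
        vol = levels[level_idx]
    else:
        vol = np.where(
            rng.random(n) < cohort.p_zero,
            0.0,
            np.minimum(
                np.exp(rng.normal(cohort.log_volume_mu, cohort.log_volume_sigma, n)),
                cohort.max_volume_cm3,
            ),
        )
    age = np.clip(np.round(rng.normal(cohort.age_mean, cohort.age_sd, n)), 41, 90)
    sex = np.where(rng.random(n) < cohort.p_male, "M", "F")
    stage = rng.choice(["I", "II", "III"], size=n, p=cohort.stage_probs)
    asct = rng.random(n) < cohort.p_asct
    # regimen tracks transplant status (transplant-eligible induction vs not)
    regimen = np.where(
        asct,
        np.where(rng.random(n) < 0.75, "VTD", "Other"),
        np.where(rng.random(n) < 0.55, "VMP", "Other"),
    )

    lp = cohort.beta_burden * np.log1p(vol) + cohort.beta_asct * asct
    rate = cohort.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if cohort.censor_rate > 0:
        t_censor = rng.exponential(1.0 / cohort.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    t_censor = np.minimum(t_censor, cohort.max_followup_days)
    pfs = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    pfs = np.maximum(pfs, 1.0)  # times are strictly positive, day resolution

    voxel_volume = float(np.prod(cohort.voxel_spacing_mm)) / 1000.0
    specs = []
    for i in range(n):
        v = float(vol[i])
        # many dispersed focal lesions, as in multifocal skeletal disease;
        # count grows with burden so high-burden subjects look diffusely
        # involved rather than dominated by one giant blob
        count = 0 if v < voxel_volume / 2 else int(min(1 + rng.poisson(v / 10.0), 40))
        if cohort.burden_level_suvs is not None and level_idx is not None:
            suv_i = float(cohort.burden_level_suvs[level_idx[i]])
        else:
            suv_i = float(rng.uniform(3.5, 8.0))
        if cohort.burden_level_bg_suvs is not None and level_idx is not None:
            # per-level diffuse marrow uptake (stays below the MTV threshold)
            bg_i = float(cohort.burden_level_bg_suvs[level_idx[i]])
        else:
            bg_i = float(rng.uniform(0.6, 1.6))
        specs.append(
            PhantomSpec(
                grid_shape=cohort.grid_shape,
                voxel_spacing_mm=cohort.voxel_spacing_mm,
                lesion_count=count,
                lesion_volume_cm3=v if count else 0.0,
                lesion_suv=suv_i,
                background_bone_suv=bg_i,
                seed=subject_seeds[i],
            )
        )

    records = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": age.astype(int),
            "sex": sex,
            "stage": stage,
            "asct": asct,
            "chemo_regimen": regimen,
            "pfs_days": pfs,
            "event": event,
            "true_lesion_volume_cm3": vol,
        }
    )
    phantoms = [generate_phantom(s) for s in specs] if volumes else None
    return Cohort(spec=cohort, records=records, phantom_specs=specs, phantoms=phantoms)
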