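"""End-to-end orchestration: phantom cohort -> bone VOIs -> PET burden
metrics -> MIPs -> autoencoder features -> clustering -> survival tables.

A single global seed fans out to per-stage seeds by fixed offsets (cohort
+0, autoencoder +1, k-means +2, supervised clustering +3), so reruns of the
whole pipeline — or of an individual stage — with the same configuration
are reproducible.  Every run writes a manifest with the configuration hash
and the seeds used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as pio
from .autoencoder import ConvAutoencoder, TrainConfig, encode_features, train_autoencoder
from .bone_voi import apply_mask, extract_bone_mask
from .clustering import (
    ClusterLabels,
    SupervisedClusterConfig,
    kmeans_cluster,
    order_clusters,
    pca_project,
    supervised_survival_cluster,
)
from .mip import make_mip
from .pet_params import conventional_params
from .phantom import Cohort, CohortSpec, simulate_cohort
from .survival import (
    categorize_by_cutpoints,
    cluster_param_stats,
    find_cutpoints,
    fit_cox,
    fit_km_logrank,
    tertile_bins,
)

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name (and subject, if applicable)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; YAML-serializable."""

    cohort: CohortSpec = CohortSpec()
    hu_threshold: float = 150.0
    min_component_voxels: int = 20
    suv_threshold: float = 2.5
    suv_cap: float = 10.0
    train: TrainConfig = TrainConfig()
    supervised: SupervisedClusterConfig = SupervisedClusterConfig()
    cutpoint_min_prop: float = 0.1
    seed: int = 0
    save_volumes: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every artifact a run produced."""

    config: PipelineConfig
    records: pd.DataFrame              # cohort table + groups + cluster labels
    params: pd.DataFrame               # per-subject conventional parameters
    features: np.ndarray               # n x 3072
    model: ConvAutoencoder
    train_history: pd.DataFrame
    unsupervised: ClusterLabels
    supervised: ClusterLabels
    mtv_cutpoints: tuple[float, ...]
    km: dict[str, object]              # variable -> KMResult
    cox_univariate: pd.DataFrame
    cox_multivariate: dict[str, pd.DataFrame]
    kruskal: dict[str, dict]
    output_dir: Path | None


def _stage(name: str, subject: str | None = None):
    tag = f"stage={name}" + (f" subject={subject}" if subject else "")
    return tag


def run_pipeline(cfg: PipelineConfig, output_dir=None) -> PipelineResult:
    """Run every stage in order; artifacts are written under ``output_dir``
    when one is given, and always returned in memory."""
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage: phantom cohort -------------------------------------------
    try:
        cohort_spec = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        cohort: Cohort = simulate_cohort(cohort_spec, volumes=False)
    except Exception as e:
        raise PipelineError(f"{_stage('phantom')}: {e}") from e
    records = cohort.records.copy()
    n = len(records)

    # ---- stages: mask / params / mip, per subject ------------------------
    mips, param_rows = [], []
    for i, sid in enumerate(records["subject_id"]):
        try:
            phantom = cohort.realize_phantom(i)
            vols = phantom.volumes
            mask = extract_bone_mask(vols.ct, cfg.hu_threshold, cfg.min_component_voxels)
            masked = apply_mask(vols.suv, mask)
            params = conventional_params(vols.suv, mask, vols.voxel_volume_cm3,
                                         cfg.suv_threshold)
            mip = make_mip(masked, suv_cap=cfg.suv_cap)
        except Exception as e:
            raise PipelineError(f"{_stage('voi/params/mip', sid)}: {e}") from e
        mips.append(mip)
        param_rows.append({"subject_id": sid, **params.as_dict()})
        if out is not None:
            pio.save_mask(mask.mask, vols.voxel_spacing_mm, out / f"{sid}.bone_mask.nii.gz")
            pio.save_mip(mip, out / sid)
            if cfg.save_volumes:
                pio.save_nifti(vols.ct, vols.voxel_spacing_mm, out / f"{sid}.ct.nii.gz")
                pio.save_nifti(vols.suv, vols.voxel_spacing_mm, out / f"{sid}.suv.nii.gz")
    params = pd.DataFrame(param_rows)

    # ---- stage: autoencoder ----------------------------------------------
    try:
        train_cfg = dataclasses.replace(cfg.train, seed=cfg.seed + 1)
        model = ConvAutoencoder(seed=cfg.seed + 1)
        train_res = train_autoencoder(model, mips, train_cfg)
        features = encode_features(model, mips)
    except Exception as e:
        raise PipelineError(f"{_stage('autoencoder')}: {e}") from e

    # ---- stage: clustering ------------------------------------------------
    try:
        mtv = params["mtv_cm3"].to_numpy()
        raw_km = kmeans_cluster(features, k=3, max_iter=300, seed=cfg.seed + 2)
        unsup = order_clusters(raw_km, mtv, method="unsupervised")
        sup_cfg = dataclasses.replace(cfg.supervised, seed=cfg.seed + 3)
        raw_sup = supervised_survival_cluster(
            features, records["pfs_days"], records["event"], sup_cfg
        )
        sup = order_clusters(raw_sup, mtv, method="supervised")
    except Exception as e:
        raise PipelineError(f"{_stage('clustering')}: {e}") from e
    records["unsupervised_cluster"] = unsup.labels
    records["supervised_cluster"] = sup.labels
    records = records.merge(params, on="subject_id")

    # ---- stage: survival ---------------------------------------------------
    try:
        cut = find_cutpoints(mtv, records["pfs_days"], records["event"],
                             min_prop=cfg.cutpoint_min_prop)
        records["mtv_group"] = categorize_by_cutpoints(mtv, cut.cutpoints)
        age_labels, age_cuts = tertile_bins(records["age"].to_numpy())
        records["age_group"] = age_labels

        km = {}
        for var in ("unsupervised_cluster", "supervised_cluster", "mtv_group",
                    "asct", "stage"):
            km[var] = fit_km_logrank(records[var].astype(str),
                                     records["pfs_days"], records["event"])

        uni_vars = ["sex", "age_group", "chemo_regimen", "asct", "stage",
                    "unsupervised_cluster", "supervised_cluster", "mtv_group"]
        uni_tables = []
        for var in uni_vars:
            try:
                fit = fit_cox(records, var, mode="univariate",
                              references={"mtv_group": "low", "age_group": "low"})
                uni_tables.append(fit.summary)
            except Exception as e:
                warnings.warn(f"univariate Cox failed for {var}: {e}", stacklevel=2)
        cox_uni = pd.concat(uni_tables, ignore_index=True) if uni_tables else pd.DataFrame()

        # one imaging variable at a time, per the multicollinearity rule;
        # chemotherapy regimen excluded (collinear with ASCT)
        base = ["age_group", "asct", "stage"]
        cox_multi = {}
        for imaging in ("unsupervised_cluster", "supervised_cluster", "mtv_group"):
            try:
                fit = fit_cox(records, base + [imaging], mode="multivariate",
                              references={"mtv_group": "low", "age_group": "low"})
                cox_multi[imaging] = fit.summary
            except Exception as e:
                warnings.warn(f"multivariate Cox failed for {imaging}: {e}", stacklevel=2)

        kruskal = {}
        for method, lab in (("unsupervised", unsup), ("supervised", sup)):
            kruskal[method] = cluster_param_stats(
                params[["suv_max", "suv_mean_voi", "mtv_cm3", "tlg"]], lab.labels
            )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"{_stage('survival')}: {e}") from e

    # ---- artifacts ---------------------------------------------------------
    if out is not None:
        _write_artifacts(out, cfg, records, params, features, model, train_res,
                         unsup, sup, cut, km, cox_uni, cox_multi)

    return PipelineResult(
        config=cfg, records=records, params=params, features=features,
        model=model, train_history=train_res.history,
        unsupervised=unsup, supervised=sup, mtv_cutpoints=cut.cutpoints,
        km=km, cox_univariate=cox_uni, cox_multivariate=cox_multi,
        kruskal=kruskal, output_dir=out,
    )


def _pca_plot(features, labels: ClusterLabels, path: Path) -> None:
    coords, _ = pca_project(features, 2)
    fig, ax = plt.subplots(figsize=(5, 4))
    for name in sorted(set(labels.labels)):
        sel = labels.labels == name
        ax.scatter(coords[sel, 0], coords[sel, 1], s=14, label=f"cluster {name}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False)
    ax.set_title(f"{labels.method} clustering")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _km_plot(km_result, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sf in km_result.curves.items():
        ax.step(sf["timeline"], sf["survival"], where="post", label=g)
    ax.set_xlabel("days")
    ax.set_ylabel("PFS probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"{title} (log-rank p={km_result.overall_p:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_artifacts(out, cfg, records, params, features, model, train_res,
                     unsup, sup, cut, km, cox_uni, cox_multi) -> None:
    records.to_csv(out / "cohort.csv", index=False)
    params.to_csv(out / "params.csv", index=False)
    feat = pd.DataFrame(features, index=records["subject_id"])
    feat.to_csv(out / "features.csv")
    train_res.history.to_csv(out / "training_log.csv", index=False)
    model.save(out / "autoencoder.npz")
    labels = pd.DataFrame(
        {
            "subject_id": records["subject_id"],
            "unsupervised_raw": unsup.raw_labels,
            "unsupervised": unsup.labels,
            "supervised_raw": sup.raw_labels,
            "supervised": sup.labels,
        }
    )
    labels.to_csv(out / "cluster_labels.csv", index=False)
    coords, _ = pca_project(features, 2)
    pd.DataFrame(
        {"subject_id": records["subject_id"], "pc1": coords[:, 0], "pc2": coords[:, 1]}
    ).to_csv(out / "pca_coords.csv", index=False)
    _pca_plot(features, unsup, out / "pca_unsupervised.png")
    _pca_plot(features, sup, out / "pca_supervised.png")
    for var, res in km.items():
        _km_plot(res, out / f"km_{var}.png", var)
        res.pairwise.to_csv(out / f"logrank_{var}.csv", index=False)
    cox_uni.to_csv(out / "cox_univariate.csv", index=False)
    for imaging, table in cox_multi.items():
        table.to_csv(out / f"cox_multivariate_{imaging}.csv", index=False)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": {"cohort": cfg.seed, "autoencoder": cfg.seed + 1,
                        "kmeans": cfg.seed + 2, "supervised": cfg.seed + 3},
        "n_subjects": int(len(records)),
        "mtv_cutpoints_cm3": [float(c) for c in cut.cutpoints],
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
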