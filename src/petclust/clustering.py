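"""Subject clustering on autoencoder features.

Two routes to three groups: plain k-means (k = 3, max 300 iterations,
k-means++ with seeded restarts) and an outcome-weighted supervised
procedure in the spirit of survClust — each standardized feature is scaled
by the magnitude of its univariate Cox log-hazard coefficient, pairwise
squared-Euclidean distances of the scaled features are embedded by
classical multidimensional scaling (equivalently, PCA of the scaled
matrix), k-means runs on the embedding, and the whole procedure is wrapped
in repeated cross-validation whose fold labelings are consensus-merged by
Hungarian matching and majority vote.  Clusters are finally renamed A/B/C
in ascending order of within-cluster mean MTV, so cluster C is always the
highest-burden group.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .survival import univariate_cox_coefficients

__all__ = [
    "ClusterLabels", "SupervisedClusterConfig",
    "kmeans_cluster", "supervised_survival_cluster", "order_clusters",
    "pca_project",
]


@dataclass(frozen=True)
class ClusterLabels:
    """Per-subject assignment with the burden-ordered A/B/C naming."""

    labels: np.ndarray          # ordered names, e.g. "A"/"B"/"C"
    raw_labels: np.ndarray      # pre-ordering integer assignment
    method: str                 # "unsupervised" | "supervised"
    mean_mtv: dict[str, float]  # per ordered label


@dataclass(frozen=True)
class SupervisedClusterConfig:
    """Settings for the outcome-weighted clustering.

    Each feature's weight is the soft-thresholded Wald statistic of its
    univariate Cox fit, ``max(|beta|/se - z_threshold, 0)``: features whose
    hazard association is indistinguishable from sampling noise carry
    weight 0, and near-separating features with wild coefficient estimates
    (common among sparse bottleneck activations) cannot dominate, because
    their standard errors blow up with them.  ``z_threshold=0`` keeps every
    feature's full Wald weight.
    """

    k: int = 3
    n_folds: int = 3
    n_rounds: int = 10
    n_components: int = 10
    z_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant features end up identically 0
    return (X - mu) / sd


def kmeans_cluster(features: np.ndarray, k: int = 3, max_iter: int = 300,
                   seed: int = 0) -> np.ndarray:
    """k-means labels on mean-centered features (k-means++, 10 restarts).

    Features are centered but deliberately not scaled to unit variance:
    autoencoder bottleneck channels are co-trained and share a natural
    scale, and per-feature variance normalization amplifies near-dead
    units' noise until it buries the burden signal the clusters should
    reflect.
    """
    X = np.asarray(features, dtype=float)
    X = X - X.mean(axis=0)
    if len(X) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(X)}")
    km = KMeans(n_clusters=k, max_iter=max_iter, n_init=10, random_state=seed)
    return km.fit_predict(X)


def _match_to_reference(labels: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Permute ``labels`` to maximize agreement with ``reference``."""
    overlap = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            overlap[a, b] = np.sum((labels == a) & (reference == b))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = dict(zip(rows, cols))
    return np.asarray([mapping[l] for l in labels])


def supervised_survival_cluster(
    features: np.ndarray,
    time,
    event,
    cfg: SupervisedClusterConfig = SupervisedClusterConfig(),
) -> np.ndarray:
    """Outcome-weighted consensus clustering of subjects.

    Per cross-validation fold: (1) univariate Cox coefficients of every
    standardized feature on the training subjects; (2) features scaled by
    the soft-thresholded Wald statistic ``max(|beta|/se - z_threshold, 0)``
    (zero-weight features drop out of every distance);
    (3) classical MDS embedding of the weighted squared-Euclidean
    distances, computed as PCA of the scaled matrix centered on the
    training rows; (4) k-means on the training embedding; (5) held-out
    subjects assigned to the nearest training centroid.  Each round x fold
    yields a full-cohort labeling; labelings are aligned to the first by
    Hungarian matching and merged by per-subject majority vote (ties to
    the lower label).  Deterministic given ``cfg.seed``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    X = _standardize(features)
    n = len(X)
    if n < cfg.k * cfg.n_folds:
        raise ValueError(f"too few subjects ({n}) for {cfg.n_folds}-fold clustering into {cfg.k}")
    if event.sum() == 0:
        raise ValueError("no observed events; outcome weights undefined")

    labelings = []
    for r in range(cfg.n_rounds):
        kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed + 1000 * r)
        for f, (train, test) in enumerate(kf.split(X)):
            if event[train].sum() == 0:
                continue  # fold carries no events; skip its labeling
            beta, se = univariate_cox_coefficients(
                X[train], time[train], event[train], return_se=True
            )
            z = np.abs(beta) / np.where(se > 0, se, np.inf)
            weights = np.maximum(z - cfg.z_threshold, 0.0)
            if not weights.any():
                weights = z  # nothing survives thresholding; fall back
            Xw = X * weights
            n_comp = int(min(cfg.n_components, len(train) - 1, Xw.shape[1]))
            pca = PCA(n_components=n_comp, random_state=cfg.seed)
            pca.fit(Xw[train])
            Z = pca.transform(Xw)
            km = KMeans(n_clusters=cfg.k, n_init=10, max_iter=300,
                        random_state=cfg.seed + 7919 * r + f)
            km.fit(Z[train])
            full = np.empty(n, dtype=int)
            full[train] = km.labels_
            d = ((Z[test][:, None, :] - km.cluster_centers_[None]) ** 2).sum(axis=2)
            full[test] = d.argmin(axis=1)
            labelings.append(full)
    if not labelings:
        raise ValueError("no cross-validation fold contained an observed event")

    reference = labelings[0]
    aligned = [reference] + [
        _match_to_reference(lab, reference, cfg.k) for lab in labelings[1:]
    ]
    votes = np.zeros((n, cfg.k), dtype=int)
    for lab in aligned:
        votes[np.arange(n), lab] += 1
    return votes.argmax(axis=1)


def order_clusters(raw_labels, mtv_cm3, method: str = "unsupervised",
                   k: int | None = None) -> ClusterLabels:
    """Rename raw clusters A, B, C, ... by ascending within-cluster mean MTV.

    Ties in mean MTV break by raw label index.  Membership is unchanged;
    only names move.
    """
    raw = np.asarray(raw_labels)
    mtv = np.asarray(mtv_cm3, dtype=float)
    if raw.shape != mtv.shape:
        raise ValueError("labels and MTV vectors differ in length")
    present = np.unique(raw)
    if k is not None and len(present) < k:
        missing = sorted(set(range(k)) - set(present.tolist()))
        raise ValueError(f"empty cluster(s): {missing}")
    means = {int(c): float(mtv[raw == c].mean()) for c in present}
    ordering = sorted(means, key=lambda c: (means[c], c))
    name_of = {c: string.ascii_uppercase[i] for i, c in enumerate(ordering)}
    labels = np.asarray([name_of[int(c)] for c in raw], dtype=object)
    mean_mtv = {name_of[c]: means[c] for c in ordering}
    return ClusterLabels(labels=labels, raw_labels=raw, method=method, mean_mtv=mean_mtv)


def pca_project(features: np.ndarray, n_components: int = 2):
    """Mean-centered PCA coordinates for visualization.

    Returns ``(coords, explained_variance)`` with component variances
    nonincreasing.  Raises on a constant feature matrix.
    """
    X = np.asarray(features, dtype=float)
    if len(X) < 2:
        raise ValueError("need >= 2 subjects")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constant feature matrix has no principal components")
    n_comp = int(min(n_components, len(X) - 1, X.shape[1]))
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X - X.mean(axis=0))
    return coords, pca.explained_variance_
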