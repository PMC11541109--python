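"""Spike sorting: alignment, feature extraction, clustering and inference.

The sorter mirrors an on-chip training/inference split.  Training aligns
detected 64-sample spikes at their maximum-slope point, extracts features
through either PCA (up to 10 components) or an adaptive-filter style
selection of discriminative sample positions (up to 7), and clusters the
feature vectors with k-means++-seeded Lloyd iterations, choosing the number
of clusters (capped at 8) by silhouette score.  Inference projects each
spike through the cached feature matrix — a plain matrix product evaluated
in blocked multiply-accumulate order — and assigns the nearest cluster under
the Euclidean or Mahalanobis metric; the covariance-weighted metric pays off
when cluster noise is anisotropic and correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .detection import SpikeEvent

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "align_max_slope",
    "pca_train",
    "af_train",
    "mac_project",
    "kmeans_train",
    "cluster_model_from_labels",
    "classify",
    "sorting_accuracy",
]

WINDOW = 64
ALIGN_INDEX = 20  # the maximum-slope sample lands here after alignment
PCA_MAX_FEATURES = 10
AF_MAX_FEATURES = 7
K_MAX = 8


@dataclass(frozen=True)
class FeatureMatrix:
    """Cached projection from 64-sample spikes to feature space.

    ``kind`` is ``"pca"`` (orthonormal rows, up to 10) or ``"af"`` (sparse
    indicator rows selecting discriminative samples, up to 7).
    """

    projection: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        proj = np.asarray(self.projection, dtype=np.float64)
        if proj.ndim != 2 or proj.shape[1] != WINDOW:
            raise ValueError(f"projection must be [n_features x {WINDOW}]")
        cap = {"pca": PCA_MAX_FEATURES, "af": AF_MAX_FEATURES}.get(self.kind)
        if cap is None:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if proj.shape[0] > cap:
            raise ValueError(f"{self.kind} supports at most {cap} features, got {proj.shape[0]}")
        object.__setattr__(self, "projection", proj)

    @property
    def n_features(self) -> int:
        return self.projection.shape[0]


@dataclass
class ClusterModel:
    """Trained cluster means (and covariances) in feature space."""

    means: np.ndarray
    covariances: np.ndarray | None = None
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        if self.means.ndim != 2:
            raise ValueError("means must be [k x n_features]")
        if self.k > K_MAX:
            raise ValueError(f"cluster count capped at {K_MAX}, got {self.k}")
        if self.metric not in ("euclidean", "mahalanobis"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric == "mahalanobis" and self.covariances is None:
            raise ValueError("mahalanobis metric requires covariances")

    @property
    def k(self) -> int:
        return self.means.shape[0]


def align_max_slope(event: SpikeEvent | np.ndarray, smooth: tuple[int, ...] | None = (1, 2, 1)) -> np.ndarray:
    """Shift a 64-sample waveform so its maximum-slope sample sits at 20.

    The first difference is smoothed with a short triangular kernel before
    the argmax (pass ``smooth=None`` for the raw difference): near-flat
    slope maxima otherwise let sample noise flip the alignment by one or
    two samples, which splinters clusters in feature space.  Ties break to
    the earliest sample; samples shifted in from outside the window are
    zero.
    """
    wf = event.waveform if isinstance(event, SpikeEvent) else np.asarray(event, dtype=np.int64)
    if wf.shape != (WINDOW,):
        raise ValueError(f"waveform must have exactly {WINDOW} samples")
    slope = np.diff(wf)
    if smooth is not None:
        slope = np.convolve(slope, np.asarray(smooth, dtype=np.int64), mode="same")
    slope_idx = int(np.argmax(slope))  # argmax takes the first maximum
    shift = slope_idx - ALIGN_INDEX
    out = np.zeros(WINDOW, dtype=wf.dtype)
    src_lo, src_hi = max(0, shift), min(WINDOW, WINDOW + shift)
    dst_lo = max(0, -shift)
    out[dst_lo : dst_lo + (src_hi - src_lo)] = wf[src_lo:src_hi]
    return out


def pca_train(S: np.ndarray, n_features: int) -> FeatureMatrix:
    """Top principal axes of the mean-centered aligned spike matrix.

    Rows are orthonormal with a deterministic sign convention: the loading
    of largest magnitude in each component is positive.
    """
    S = np.asarray(S, dtype=np.float64)
    if n_features > PCA_MAX_FEATURES:
        raise ValueError(f"PCA supports at most {PCA_MAX_FEATURES} features")
    if S.shape[0] <= n_features:
        raise ValueError("need more spikes than features")
    centered = S - S.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:n_features]
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return FeatureMatrix(projection=comps, kind="pca")


def af_train(S: np.ndarray, labels: np.ndarray, n_features: int) -> FeatureMatrix:
    """Select discriminative sample positions from provisionally labeled spikes.

    Scores each of the 64 sample positions by its between-class /
    within-class variance ratio and keeps the top ``n_features`` positions
    as a sparse indicator projection (ties to the lower index).
    """
    S = np.asarray(S, dtype=np.float64)
    labels = np.asarray(labels)
    if n_features > AF_MAX_FEATURES:
        raise ValueError(f"AF supports at most {AF_MAX_FEATURES} features")
    if S.shape[0] != labels.shape[0]:
        raise ValueError("one label per spike required")
    classes = np.unique(labels)
    overall = S.mean(axis=0)
    between = np.zeros(WINDOW)
    within = np.zeros(WINDOW)
    for cls in classes:
        grp = S[labels == cls]
        between += grp.shape[0] * (grp.mean(axis=0) - overall) ** 2
        within += grp.shape[0] * grp.var(axis=0)
    scores = between / (within + 1e-12)
    order = np.lexsort((np.arange(WINDOW), -scores))
    picks = np.sort(order[:n_features])
    proj = np.zeros((n_features, WINDOW))
    proj[np.arange(n_features), picks] = 1.0
    return FeatureMatrix(projection=proj, kind="af")


def mac_project(S: np.ndarray, F: FeatureMatrix, block: int = 16) -> np.ndarray:
    """Project spikes into feature space: ``S @ F.projection.T``.

    Evaluated in blocked row-by-column multiply-accumulate order (the MAC
    tiling); the result matches the plain matrix product up to float
    round-off regardless of the block size.
    """
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    if S.shape[1] != F.projection.shape[1]:
        raise ValueError("spike length and projection width disagree")
    out = np.zeros((S.shape[0], F.n_features))
    for k0 in range(0, S.shape[1], block):
        out += S[:, k0 : k0 + block] @ F.projection.T[k0 : k0 + block]
    return out


def _regularized_covariances(features: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Per-cluster covariance with ridge 1e-3 * trace / d on the diagonal."""
    d = features.shape[1]
    covs = np.empty((k, d, d))
    for c in range(k):
        pts = features[labels == c]
        cov = np.cov(pts.T) if pts.shape[0] > 1 else np.eye(d)
        cov = np.atleast_2d(cov)
        ridge = 1e-3 * np.trace(cov) / d + 1e-9
        covs[c] = cov + ridge * np.eye(d)
    return covs


def kmeans_train(
    features: np.ndarray,
    k_max: int = K_MAX,
    seed: int = 0,
    *,
    k: int | None = None,
    metric: str = "euclidean",
    min_cluster_frac: float = 0.1,
) -> ClusterModel:
    """k-means++-seeded Lloyd clustering with silhouette-based k selection.

    ``k`` forces a cluster count; otherwise each k in 2..k_max is fit and
    the best silhouette wins among clusterings whose smallest cluster
    holds at least ``min_cluster_frac`` of the spikes (clusterings that
    merely split off a handful of outlier waveforms are rejected; if every
    candidate fails the size rule the constraint is dropped).
    Deterministic given the seed.  Per-cluster covariances are computed
    and regularized for Mahalanobis inference.
    """
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if k_max > K_MAX:
        raise ValueError(f"cluster count capped at {K_MAX}")
    if k is not None:
        if k > k_max or n < k:
            raise ValueError(f"need at least {k} spikes for {k} clusters (cap {k_max})")
        best = KMeans(n_clusters=k, n_init=10, random_state=seed, tol=1e-6, max_iter=100).fit(features)
    else:
        if n < 2:
            raise ValueError("need at least 2 spikes to cluster")
        min_size = max(2, int(np.ceil(min_cluster_frac * n)))
        candidates = []
        for kk in range(2, min(k_max, n - 1) + 1):
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed, tol=1e-6, max_iter=100).fit(features)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(features, km.labels_)
            smallest = int(np.bincount(km.labels_).min())
            candidates.append((km, score, smallest))
        if not candidates:
            raise ValueError("could not find a valid clustering")
        admissible = [c for c in candidates if c[2] >= min_size] or candidates
        best = max(admissible, key=lambda c: c[1])[0]
    covs = _regularized_covariances(features, best.labels_, best.n_clusters)
    return ClusterModel(means=best.cluster_centers_, covariances=covs, metric=metric)


def cluster_model_from_labels(features: np.ndarray, labels: np.ndarray, metric: str = "euclidean") -> ClusterModel:
    """Build a model directly from labeled features (supervised reference)."""
    features = np.asarray(features, dtype=np.float64)
    classes = np.unique(labels)
    if classes.size > K_MAX:
        raise ValueError(f"cluster count capped at {K_MAX}")
    remap = {c: i for i, c in enumerate(classes)}
    idx = np.asarray([remap[v] for v in labels])
    means = np.stack([features[idx == i].mean(axis=0) for i in range(classes.size)])
    covs = _regularized_covariances(features, idx, classes.size)
    return ClusterModel(means=means, covariances=covs, metric=metric)


def classify(features: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Nearest-cluster assignment; ties resolve to the lowest cluster id."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    diffs = features[:, None, :] - model.means[None, :, :]  # [n, k, d]
    if model.metric == "euclidean":
        dist = np.einsum("nkd,nkd->nk", diffs, diffs)
    else:
        inv = np.linalg.inv(model.covariances)  # [k, d, d]
        dist = np.einsum("nkd,kde,nke->nk", diffs, inv, diffs)
    return np.argmin(dist, axis=1)


def sorting_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Accuracy (%) under the best one-to-one cluster-template assignment.

    Builds the confusion matrix and solves the optimal bipartite matching,
    so cluster numbering does not matter.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label lists must have equal length")
    if predicted.size == 0:
        return 0.0
    p_ids, p_idx = np.unique(predicted, return_inverse=True)
    t_ids, t_idx = np.unique(truth, return_inverse=True)
    confusion = np.zeros((p_ids.size, t_ids.size), dtype=np.int64)
    np.add.at(confusion, (p_idx, t_idx), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return 100.0 * confusion[rows, cols].sum() / predicted.size
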