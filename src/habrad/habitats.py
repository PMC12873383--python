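"""K-means habitat segmentation of VOI voxels.

A single k-means model is fitted on voxel feature vectors pooled across the
training cohort and then applied to every subject, so habitat label j means
the same tissue signature in every subject — the property that makes
per-habitat feature tables comparable across the cohort.  Features are
z-scored with pooled training statistics before clustering, and cluster
indices are relabelled by ascending centroid value in the T2W Median
column so H1..Hk are reproducible across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics import silhouette_score as _sk_silhouette

from .imaging import Mask
from .voxel_features import matrix_column_names

logger = logging.getLogger(__name__)

#: column used for the deterministic relabelling convention
_RELABEL_COLUMN = "T2W_Median"


@dataclass
class HabitatModel:
    """A fitted, standardized k-means habitat model."""

    k: int
    centroids: np.ndarray            # (k, n_used) in standardized space
    mean: np.ndarray                 # per-column standardization mean
    std: np.ndarray                  # per-column standardization std
    used_columns: np.ndarray         # indices of non-constant columns kept
    n_features: int
    seed: int = 0
    n_init: int = 10

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "used_columns": self.used_columns.tolist(),
            "n_features": self.n_features,
            "seed": self.seed,
            "n_init": self.n_init,
        })

    @classmethod
    def from_json(cls, text: str) -> "HabitatModel":
        d = json.loads(text)
        return cls(d["k"], np.asarray(d["centroids"]), np.asarray(d["mean"]),
                   np.asarray(d["std"]), np.asarray(d["used_columns"]),
                   d["n_features"], d["seed"], d["n_init"])

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if matrix.shape[1] != self.n_features:
            raise ValueError(
                f"matrix has {matrix.shape[1]} features, model expects "
                f"{self.n_features}"
            )
        return (matrix[:, self.used_columns] - self.mean) / self.std


@dataclass
class HabitatMap:
    """Integer habitat labels: 0 outside the VOI, 1..k inside."""

    labels: np.ndarray
    k: int
    subject_id: str = ""

    def __post_init__(self):
        if self.labels.max() > self.k:
            raise ValueError("habitat labels exceed k")


def fit_habitats(pooled_matrix: np.ndarray, k: int, seed: int = 0,
                 n_init: int = 10) -> HabitatModel:
    """Fit k-means on pooled, z-scored voxel features.

    ``k=1`` returns the global centroid.  Zero-variance columns are dropped
    (logged) before standardization.  Cluster order follows ascending
    centroid T2W-Median so repeated fits are bit-identical.
    """
    X = np.asarray(pooled_matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("pooled matrix must be 2-D")
    n, p = X.shape
    if n < k:
        raise ValueError(f"{n} voxels cannot support k={k} clusters")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    used = np.flatnonzero(std > 0)
    if len(used) < p:
        logger.info("dropping %d zero-variance voxel-feature columns",
                    p - len(used))
    if len(used) == 0:
        raise ValueError("all voxel-feature columns are constant")
    Z = (X[:, used] - mean[used]) / std[used]
    if k == 1:
        centroids = Z.mean(axis=0, keepdims=True)
    else:
        if len(np.unique(Z, axis=0)) < k:
            raise ValueError(f"fewer than k={k} distinct voxel vectors")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                    init="k-means++")
        km.fit(Z)
        centroids = km.cluster_centers_
        order = _relabel_order(centroids, used)
        centroids = centroids[order]
    return HabitatModel(k, centroids, mean[used], std[used], used, p,
                        seed, n_init)


def _relabel_order(centroids: np.ndarray, used: np.ndarray) -> np.ndarray:
    names = matrix_column_names()
    target = names.index(_RELABEL_COLUMN)
    pos = np.flatnonzero(used == target)
    col = centroids[:, pos[0]] if len(pos) else centroids[:, 0]
    return np.argsort(col, kind="stable")


def assign_habitats(model: HabitatModel, matrix: np.ndarray,
                    coords: np.ndarray, grid_shape, subject_id: str = ""
                    ) -> HabitatMap:
    """Nearest-centroid assignment; ties go to the lowest habitat index."""
    Z = model.transform(np.asarray(matrix, dtype=np.float64))
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    labels1 = np.argmin(d2, axis=1) + 1  # argmin takes the first minimum
    vol = np.zeros(tuple(grid_shape), dtype=np.int32)
    vol[tuple(np.asarray(coords).T)] = labels1
    return HabitatMap(vol, model.k, subject_id)


def silhouette(matrix: np.ndarray, labels: np.ndarray,
               sample_cap: int = 10_000, seed: int = 0) -> float:
    """Mean silhouette over a seeded subsample of at most ``sample_cap``.

    Euclidean distances; singleton clusters contribute 0 (scikit-learn's
    convention).  Undefined for fewer than two occupied clusters.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = len(labels)
    sample_size = min(sample_cap, n)
    if sample_size < n:
        return float(_sk_silhouette(matrix, labels, sample_size=sample_size,
                                    random_state=seed))
    return float(_sk_silhouette(matrix, labels))


def recover_ari(habitat_map: HabitatMap, truth_labels: np.ndarray) -> float:
    """Adjusted Rand index between a habitat map and planted truth, on VOI."""
    truth_labels = np.asarray(truth_labels)
    if truth_labels.shape != habitat_map.labels.shape:
        raise ValueError("truth grid does not match habitat map grid")
    voi = truth_labels > 0
    return float(adjusted_rand_score(truth_labels[voi],
                                     habitat_map.labels[voi]))


def habitat_map_from_model(model: HabitatModel, matrix, coords, mask: Mask,
                           subject_id: str = "") -> HabitatMap:
    return assign_habitats(model, matrix, coords, mask.shape, subject_id)
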