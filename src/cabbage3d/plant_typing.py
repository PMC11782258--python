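"""Unsupervised plant-type discovery from trait vectors.

Trait matrices are z-scored column-wise, clustered by K-medoids with the
Voronoi-style alternation (assign to nearest medoid, re-elect each cluster's
medoid as the member minimizing summed intra-cluster distance, repeat until
the labels stabilize), the cluster count is selected by the silhouette
coefficient over k = 2..8 with the k-means WCSS elbow reported as a second
diagnostic, and for k = 4 the clusters are named by a deterministic rank-sum
rule over their centroid traits:

1. TIGHT is the cluster with the smallest V + S3 rank-sum (compact, small
   hull and footprint);
2. ROUND_SPREAD is the remaining cluster with the largest S3 + O rank-sum
   (wide, round footprint);
3. of the last two, HIGHLY_LEAN has the larger height-to-spread ratio T and
   FULL is what remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.cluster import KMeans

from .errors import ValidationError
from .traits import TRAIT_NAMES

__all__ = [
    "TypeLabel",
    "StandardizedMatrix",
    "ClusterModel",
    "zscore_standardize",
    "kmedoids",
    "silhouette_score",
    "wcss_curve",
    "select_k",
    "assign_type_labels",
]


class TypeLabel(str, Enum):
    """The four discovered rosette architectures."""

    FULL = "FULL"
    HIGHLY_LEAN = "HIGHLY_LEAN"
    TIGHT = "TIGHT"
    ROUND_SPREAD = "ROUND_SPREAD"


@dataclass
class StandardizedMatrix:
    """Column-wise z-scored trait matrix with the fit statistics attached."""

    values: np.ndarray        # (n, p)
    col_means: np.ndarray     # (p,)
    col_sds: np.ndarray       # (p,) sample sd (ddof=1); 1.0 recorded for constants
    trait_names: tuple = TRAIT_NAMES
    constant_cols: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterModel:
    """A fitted K-medoids partition."""

    k: int
    medoid_indices: np.ndarray   # (k,) row indices into the data
    labels: np.ndarray           # (n,) cluster ids in [0, k)
    total_cost: float            # sum of distances to assigned medoids
    centroid_traits: np.ndarray | None  # (k, p) mean raw traits per cluster
    iterations: int
    trait_names: tuple = TRAIT_NAMES


def zscore_standardize(matrix: np.ndarray,
                       trait_names: tuple = TRAIT_NAMES) -> StandardizedMatrix:
    """Per-column (x - mean) / sd with sample sd (ddof=1).

    Constant columns cannot be scaled; they are set to all-zero, flagged, and
    a warning is emitted.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("standardization needs a 2D matrix with n >= 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = sds <= 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant trait column(s) set to zero",
                      stacklevel=2)
    safe_sds = np.where(constant, 1.0, sds)
    Z = (X - means) / safe_sds
    Z[:, constant] = 0.0
    return StandardizedMatrix(Z, means, safe_sds, tuple(trait_names), constant)


def _assign(X: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    d = np.linalg.norm(X[:, None, :] - X[medoids][None, :, :], axis=2)
    labels = np.argmin(d, axis=1)  # argmin resolves ties toward the lowest index
    cost = float(d[np.arange(X.shape[0]), labels].sum())
    return labels, cost


def kmedoids(sm: StandardizedMatrix | np.ndarray, k: int, seed: int = 0,
             max_iter: int = 300, n_restarts: int = 10,
             raw_traits: np.ndarray | None = None) -> ClusterModel:
    """K-medoids by Voronoi iteration, best of ``n_restarts`` seeded starts.

    Each restart draws k distinct initial medoids, alternates assignment and
    medoid re-election until the labels stop changing (or ``max_iter``), and
    the restart with the lowest total cost wins.  All ties (assignment,
    medoid election, restart comparison) break toward the lowest index, so the
    result is a deterministic function of (data, k, seed).
    """
    X = sm.values if isinstance(sm, StandardizedMatrix) else np.asarray(sm, float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        labels, cost = _assign(X, medoids)
        iterations = 0
        for iterations in range(1, max_iter + 1):
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    continue  # empty cluster keeps its medoid
                d = np.linalg.norm(X[members][:, None, :] - X[members][None, :, :],
                                   axis=2)
                within = d.sum(axis=1)
                new_medoids[c] = members[int(np.argmin(within))]
            new_labels, new_cost = _assign(X, new_medoids)
            medoids = new_medoids
            if np.array_equal(new_labels, labels):
                labels, cost = new_labels, new_cost
                break
            labels, cost = new_labels, new_cost
        if best is None or cost < best[1] - 1e-12:
            best = (medoids, cost, labels, iterations)
    medoids, cost, labels, iterations = best
    centroids = None
    if raw_traits is not None:
        raw = np.asarray(raw_traits, dtype=float)
        centroids = np.vstack([raw[labels == c].mean(axis=0) if (labels == c).any()
                               else np.full(raw.shape[1], np.nan) for c in range(k)])
    names = sm.trait_names if isinstance(sm, StandardizedMatrix) else TRAIT_NAMES
    return ClusterModel(k, medoids, labels, cost, centroids, iterations, names)


def silhouette_score(sm: StandardizedMatrix | np.ndarray, labels) -> float:
    """Mean silhouette coefficient ``(b - a) / max(a, b)`` over all points.

    ``a`` is the mean distance to the point's own cluster (excluding itself);
    ``b`` the smallest mean distance to any other cluster.  Points in
    singleton clusters contribute 0.
    """
    X = sm.values if isinstance(sm, StandardizedMatrix) else np.asarray(sm, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    n = X.shape[0]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue  # singleton: contributes 0
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def wcss_curve(sm: StandardizedMatrix | np.ndarray, k_range, seed: int = 0,
               n_restarts: int = 10) -> dict[int, float]:
    """Within-cluster sum of squares per k, by best-of-restarts Lloyd k-means."""
    X = sm.values if isinstance(sm, StandardizedMatrix) else np.asarray(sm, float)
    n = X.shape[0]
    out: dict[int, float] = {}
    for k in k_range:
        if not 1 <= k <= n:
            raise ValidationError(f"k must be in [1, {n}], got {k}")
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=seed % (2 ** 32)).fit(X)
        out[int(k)] = float(km.inertia_)
    return out


def select_k(sm: StandardizedMatrix | np.ndarray, k_range=range(2, 9),
             seed: int = 0, n_restarts: int = 10
             ) -> tuple[int, dict[int, float], dict[int, float]]:
    """Pick k by maximal K-medoids silhouette; ties go to the smallest k.

    Returns (k_best, silhouette per k, WCSS per k); the WCSS elbow curve is a
    diagnostic only and does not influence the choice.
    """
    k_range = list(k_range)
    sil: dict[int, float] = {}
    for k in k_range:
        model = kmedoids(sm, k, seed=seed, n_restarts=n_restarts)
        sil[int(k)] = silhouette_score(sm, model.labels)
    wcss = wcss_curve(sm, k_range, seed=seed, n_restarts=n_restarts)
    k_best = max(sorted(sil), key=lambda k: sil[k])  # ties -> lowest k
    return int(k_best), sil, wcss


def assign_type_labels(centroid_traits: np.ndarray,
                       trait_names: tuple = TRAIT_NAMES) -> dict[int, TypeLabel]:
    """Name four clusters from their centroid traits by the rank-sum rules.

    Ranks are computed per trait column over the k centroids (0 = smallest).
    Rank-sum ties break by the first criterion in the rule (V for TIGHT,
    S3 for ROUND_SPREAD).
    """
    C = np.asarray(centroid_traits, dtype=float)
    if C.ndim != 2 or C.shape[0] != 4:
        raise ValidationError(
            "type naming is defined for exactly 4 clusters; label other k manually")
    names = list(trait_names)
    col = {t: names.index(t) for t in ("T", "V", "S3", "O")}
    ranks = np.argsort(np.argsort(C, axis=0), axis=0).astype(float)  # 0 = smallest

    remaining = list(range(4))
    mapping: dict[int, TypeLabel] = {}

    def pick(score, tiebreak, take_max):
        best = None
        for i in remaining:
            key = (score[i], tiebreak[i], -i if take_max else i)
            if best is None:
                best = (key, i)
            elif (key > best[0]) if take_max else (key < best[0]):
                best = (key, i)
        return best[1]

    tight = pick(ranks[:, col["V"]] + ranks[:, col["S3"]], ranks[:, col["V"]],
                 take_max=False)
    mapping[tight] = TypeLabel.TIGHT
    remaining.remove(tight)

    round_spread = pick(ranks[:, col["S3"]] + ranks[:, col["O"]], ranks[:, col["S3"]],
                        take_max=True)
    mapping[round_spread] = TypeLabel.ROUND_SPREAD
    remaining.remove(round_spread)

    a, b = remaining
    if C[a, col["T"]] >= C[b, col["T"]]:
        mapping[a], mapping[b] = TypeLabel.HIGHLY_LEAN, TypeLabel.FULL
    else:
        mapping[a], mapping[b] = TypeLabel.FULL, TypeLabel.HIGHLY_LEAN
    return mapping
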