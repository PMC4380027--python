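"""k-means clustering with class-informed initialization, and its scoring.

The clustering protocol: centroids start at class means (the target
family's mean, plus the non-target mean for K=2; for K>2 the non-target
rows are pre-split by a seeded k-means++ draw and their group means
used), Lloyd iterations with Euclidean distance run until the assignment
stabilizes, and the cluster holding the most target peptides becomes the
"target cluster".  Everything downstream is scored from the resulting
confusion counts: a target peptide in the target cluster is a true
positive, a non-target peptide there a false positive, and so on.

Metrics: accuracy, sensitivity (recall), specificity, precision,
F-measure = 2TP/(2TP+FN+FP), Jaccard = TP/(TP+FP+FN), plus the external
clustering criteria entropy (cluster-size-weighted class entropy, bits)
and purity (fraction of peptides in their cluster's dominant class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import LabeledMatrix


@dataclass
class ClusteringResult:
    K: int
    assignment: np.ndarray  # row -> cluster index
    centroids: np.ndarray  # K x n_features
    target_cluster: int
    iterations: int


@dataclass
class EvaluationMetrics:
    """Confusion counts and the derived clustering-quality scores."""

    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    jaccard: float
    entropy: float
    purity: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _kmeanspp_centers(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded k-means++ center draw among the rows of X."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(n)])
            continue
        probs = d2 / total
        centers.append(X[rng.choice(n, p=probs)])
    return np.array(centers)


def init_centroids(
    matrix: LabeledMatrix, K: int, seed: int = 0
) -> np.ndarray:
    """Class-mean centroid initialization.

    Centroid 0 is the mean of the target rows.  For K=2 the second
    centroid is the non-target mean; for K>2 the non-target rows are
    grouped around K-1 seeded k-means++ centers and the group means are
    used (a group left empty falls back to its center).
    """
    n = matrix.X.shape[0]
    if not 2 <= K <= n:
        raise ValueError(f"K={K} out of range [2, {n}]")
    target_mean = matrix.X[matrix.y].mean(axis=0)
    nontarget = matrix.X[~matrix.y]
    if K == 2:
        return np.vstack([target_mean, nontarget.mean(axis=0)])
    if K - 1 > nontarget.shape[0]:
        raise ValueError(
            f"K-1={K - 1} groups but only {nontarget.shape[0]} non-target rows"
        )
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_centers(nontarget, K - 1, rng)
    d2 = ((nontarget[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    groups = d2.argmin(axis=1)
    means = []
    for g in range(K - 1):
        members = nontarget[groups == g]
        means.append(members.mean(axis=0) if len(members) else centers[g])
    return np.vstack([target_mean] + means)


def kmeans(
    X: np.ndarray,
    centroids: np.ndarray,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Lloyd iterations from the given centroids until assignments settle.

    Squared Euclidean distance (order-equivalent to Euclidean) decides
    assignments; an emptied cluster is reseeded to the point currently
    farthest from its own centroid.  Returns (assignment, centroids,
    iterations).
    """
    if not np.isfinite(X).all() or not np.isfinite(centroids).all():
        raise ValueError("non-finite values")
    if X.shape[0] < 1:
        raise ValueError("empty matrix")
    centroids = centroids.copy()
    K = centroids.shape[0]
    prev = None
    assignment = None
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assignment = d2.argmin(axis=1)
        point_d2 = d2[np.arange(len(X)), assignment]
        for k in range(K):
            if not (assignment == k).any():
                far = int(point_d2.argmax())
                assignment[far] = k
                point_d2[far] = 0.0
        if prev is not None and np.array_equal(assignment, prev):
            return assignment, centroids, it
        prev = assignment.copy()
        for k in range(K):
            centroids[k] = X[assignment == k].mean(axis=0)
    return assignment, centroids, max_iter


def cluster(
    matrix: LabeledMatrix, K: int, seed: int = 0, max_iter: int = 300
) -> ClusteringResult:
    """init_centroids + kmeans + target-cluster identification."""
    centroids = init_centroids(matrix, K, seed=seed)
    assignment, centroids, iterations = kmeans(matrix.X, centroids, max_iter)
    target_cluster = _target_cluster(assignment, matrix.y, K)
    return ClusteringResult(
        K=K,
        assignment=assignment,
        centroids=centroids,
        target_cluster=target_cluster,
        iterations=iterations,
    )


def _target_cluster(assignment: np.ndarray, y: np.ndarray, K: int) -> int:
    """Cluster with the most target rows; ties go to the lower index."""
    counts = np.array([(y & (assignment == k)).sum() for k in range(K)])
    return int(counts.argmax())


def evaluate(result: ClusteringResult, y: np.ndarray) -> EvaluationMetrics:
    """Score a clustering against binary target labels."""
    y = np.asarray(y, dtype=bool)
    if not y.any():
        raise ValueError("no target rows")
    assignment = result.assignment
    K = result.K
    tc = _target_cluster(assignment, y, K)
    in_tc = assignment == tc
    TP = int((y & in_tc).sum())
    FP = int((~y & in_tc).sum())
    FN = int((y & ~in_tc).sum())
    TN = int((~y & ~in_tc).sum())
    n = len(y)

    sensitivity = TP / (TP + FN) if TP + FN else 0.0
    specificity = TN / (TN + FP) if TN + FP else 0.0
    precision = TP / (TP + FP) if TP + FP else 0.0
    f_measure = 2 * TP / (2 * TP + FN + FP) if 2 * TP + FN + FP else 0.0
    jaccard = TP / (TP + FP + FN) if TP + FP + FN else 0.0
    accuracy = (TP + TN) / n

    entropy = 0.0
    purity = 0.0
    for k in range(K):
        members = assignment == k
        nk = members.sum()
        if nk == 0:
            continue
        pos = (y & members).sum()
        purity += max(pos, nk - pos) / n
        for c in (pos, nk - pos):
            if c:
                p = c / nk
                entropy -= (nk / n) * p * np.log2(p)

    return EvaluationMetrics(
        TP=TP,
        TN=TN,
        FP=FP,
        FN=FN,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f_measure=f_measure,
        jaccard=jaccard,
        entropy=float(entropy),
        purity=float(purity),
    )


METRIC_COLUMNS = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f_measure",
    "jaccard",
    "entropy",
    "purity",
)


def write_metrics_report(metrics: EvaluationMetrics, path, extra: dict | None = None) -> None:
    """One-row TSV of the full metric battery (plus optional id columns)."""
    extra = extra or {}
    with open(path, "w", encoding="utf-8") as fh:
        header = list(extra) + ["TP", "TN", "FP", "FN"] + list(METRIC_COLUMNS)
        fh.write("\t".join(header) + "\n")
        vals = [str(v) for v in extra.values()]
        vals += [str(getattr(metrics, c)) for c in ("TP", "TN", "FP", "FN")]
        vals += [f"{getattr(metrics, c):.6f}" for c in METRIC_COLUMNS]
        fh.write("\t".join(vals) + "\n")
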