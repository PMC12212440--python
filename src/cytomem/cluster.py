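"""Row z-scoring and seeded k-means behavioral clustering.

Induced peaks are clustered on their z-scored signal profile across
conditions (the heatmap view of the data). Lloyd's algorithm with
k-means++ seeding is run from a seeded generator with a fixed number of
restarts, keeping the solution with the lowest within-cluster sum of
squares (WCSS); the per-iteration WCSS trajectory is retained and checked
to be non-increasing. Clusters are then given semantic labels from their
mean trends: for washout clustering, descending (post-washout z minus
acute-stimulation z) maps onto {augment, persist, decay}; for acute
clustering a bipartite assignment maps clusters onto
{lps_specific, shared_jak, ifng_specific} condition signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "zscore_rows",
    "kmeans",
    "KMeansResult",
    "cluster_behaviors",
    "label_washout_clusters",
    "label_acute_clusters",
]

WASHOUT_LABELS = ("augment", "persist", "decay")
ACUTE_LABELS = ("lps_specific", "shared_jak", "ifng_specific")


def zscore_rows(values, ddof: int = 1) -> np.ndarray:
    """Per-row z-score: subtract the mean, divide by the sample sd (n-1).

    Constant rows map to all-zero. A single-column input is an error — a
    one-point profile has no shape to standardize.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D feature x condition matrix")
    if x.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 columns per row")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    return np.where(sd > 0, z, 0.0)


@dataclass
class KMeansResult:
    labels: np.ndarray
    centers: np.ndarray
    wcss: float
    n_iter: int
    wcss_history: list[float] = field(repr=False)
    seed: int = 0
    n_restarts: int = 1


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = x[rng.integers(n)]
            continue
        centers[j] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    x: np.ndarray, centers: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    history: list[float] = []
    labels = np.zeros(x.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = cdist(x, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(x.shape[0]), labels].sum())
        # an empty cluster grabs the point farthest from its center
        for j in range(centers.shape[0]):
            if not (labels == j).any():
                far = int(d2[np.arange(x.shape[0]), labels].argmax())
                labels[far] = j
        if history and wcss > history[-1] + 1e-9 * (1.0 + history[-1]):
            raise RuntimeError("WCSS increased across Lloyd iterations")
        converged = bool(history) and history[-1] - wcss <= 1e-12 * (1.0 + wcss)
        history.append(wcss)
        new_centers = np.vstack([x[labels == j].mean(axis=0) for j in range(centers.shape[0])])
        if converged or np.allclose(new_centers, centers):
            centers = new_centers
            break
        centers = new_centers
    return labels, centers, history


def kmeans(
    x,
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
    max_iter: int = 300,
) -> KMeansResult:
    """Best-of-restarts Lloyd k-means, deterministic given ``seed``.

    ``k=1`` is allowed (degenerate: one cluster, WCSS = total variance
    around the grand centroid).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of features ({x.shape[0]})")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(n_restarts):
        centers0 = _kmeanspp_init(x, k, rng)
        labels, centers, history = _lloyd(x, centers0, max_iter)
        wcss = history[-1]
        if best is None or wcss < best.wcss:
            best = KMeansResult(
                labels=labels,
                centers=centers,
                wcss=wcss,
                n_iter=len(history),
                wcss_history=history,
                seed=seed,
                n_restarts=n_restarts,
            )
    assert best is not None
    return best


def label_washout_clusters(
    result: KMeansResult,
    z: np.ndarray,
    washout_cols: list[int],
    stim_cols: list[int],
) -> dict[int, str]:
    """Map cluster ids to {augment, persist, decay} by washout trend.

    Clusters are ordered by descending (mean z in post-washout columns
    minus mean z in acute-stimulation columns): the biggest further
    increase is ``augment``, the biggest loss is ``decay``. Requires k=3.
    """
    k = result.centers.shape[0]
    if k != len(WASHOUT_LABELS):
        raise ValueError(f"washout labeling requires k={len(WASHOUT_LABELS)}")
    deltas = []
    for j in range(k):
        members = z[result.labels == j]
        delta = members[:, washout_cols].mean() - members[:, stim_cols].mean()
        deltas.append(delta)
    order = np.argsort(deltas)[::-1]
    return {int(cid): WASHOUT_LABELS[rank] for rank, cid in enumerate(order)}


def label_acute_clusters(
    result: KMeansResult,
    z: np.ndarray,
    ifng_cols: list[int],
    lps_cols: list[int],
    lps_rux_cols: list[int],
) -> dict[int, str]:
    """Map clusters onto acute stimulus-specificity classes.

    Scores each cluster against the three expected signatures
    (ruxolitinib-resistant LPS signal -> lps_specific; joint IFNγ+LPS
    signal lost under ruxolitinib -> shared_jak; IFNγ-dominant ->
    ifng_specific) and solves the bijective assignment maximizing total
    score. Requires k=3.
    """
    k = result.centers.shape[0]
    if k != len(ACUTE_LABELS):
        raise ValueError(f"acute labeling requires k={len(ACUTE_LABELS)}")
    score = np.zeros((k, 3))
    for j in range(k):
        members = z[result.labels == j]
        z_ifng = members[:, ifng_cols].mean()
        z_lps = members[:, lps_cols].mean()
        z_rux = members[:, lps_rux_cols].mean()
        score[j] = [z_rux, z_ifng + z_lps - 2 * z_rux, z_ifng - z_lps]
    rows, cols = linear_sum_assignment(-score)
    return {int(r): ACUTE_LABELS[c] for r, c in zip(rows, cols)}


def _silhouette(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    from sklearn.metrics import silhouette_samples

    if len(set(labels.tolist())) < 2 or x.shape[0] <= len(set(labels.tolist())):
        return np.zeros(x.shape[0])
    return silhouette_samples(x, labels)


def cluster_behaviors(
    values,
    feature_ids: list[str],
    washout_cols: list[int],
    stim_cols: list[int],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[pd.DataFrame, KMeansResult]:
    """Z-score rows, cluster, and label washout behaviors.

    Returns a per-feature assignment table (feature_id, cluster_id,
    cluster_label, silhouette) and the raw k-means result. ``k`` must be
    at least 2 and at most the number of features; semantic labels are
    attached only for k=3, otherwise clusters are labeled by trend rank.
    """
    if k < 2:
        raise ValueError("k must be >= 2 for behavioral clustering")
    z = zscore_rows(values)
    result = kmeans(z, k=k, seed=seed, n_restarts=n_restarts)
    if k == 3:
        label_map = label_washout_clusters(result, z, washout_cols, stim_cols)
    else:
        deltas = [
            z[result.labels == j][:, washout_cols].mean()
            - z[result.labels == j][:, stim_cols].mean()
            for j in range(k)
        ]
        order = np.argsort(deltas)[::-1]
        label_map = {int(cid): f"trend_rank_{rank}" for rank, cid in enumerate(order)}
    table = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "cluster_id": result.labels,
            "cluster_label": [label_map[int(c)] for c in result.labels],
            "silhouette": _silhouette(z, result.labels),
        }
    )
    return table, result
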