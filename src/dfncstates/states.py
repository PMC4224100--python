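"""Connectivity-state identification by exemplar-seeded k-means.

High-variability windows are selected per subject as exemplars; k-means on
the pooled exemplars (best of several replicates) yields seed centroids,
which initialize a final clustering of every window of every subject. The
number of states is chosen by the elbow of the within/between
cluster-distance ratio. Per-subject summaries (state centroids, dwell
fractions, transition and entry counts) feed the group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from dfncstates.dynamic_fnc import DynFNC

__all__ = [
    "StateModel",
    "SubjectStateSummary",
    "select_exemplars",
    "kmeans_fit",
    "choose_k_elbow",
    "cluster_states",
    "subject_summary",
]

_METRICS = ("l1", "correlation", "cosine")


@dataclass
class StateModel:
    k: int
    centroids: np.ndarray  # (k, n_edges), Fisher-z
    assignments: dict[str, np.ndarray]  # subject -> per-window labels (0-based)
    counts: np.ndarray  # (k,) window counts per state
    percentages: np.ndarray  # (k,) occurrence percentages
    metric: str
    group_centroids: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SubjectStateSummary:
    centroids: dict[int, np.ndarray]  # state -> mean of member windows
    visited: np.ndarray  # (k,) bool
    dwell_fractions: np.ndarray  # (k,)
    n_transitions: int
    entries: np.ndarray  # (k,) entry counts per state


def select_exemplars(dfnc: DynFNC) -> np.ndarray:
    """Indices of high-variability windows used to seed clustering.

    Per window the variability is the SD of the vectorized connectivity
    across edges; exemplars are the strict local maxima of that series,
    with an endpoint included when it exceeds its single neighbor. A
    constant variability series falls back to uniform subsampling.
    """
    vecs = dfnc.edge_vectors()
    W = vecs.shape[0]
    if W < 3:
        raise ValueError("need at least 3 windows to pick exemplars")
    var = vecs.std(axis=1)
    if np.allclose(var, var[0]):
        warnings.warn("constant variability series; uniform subsampling fallback")
        return np.arange(0, W, max(1, W // 10))
    picks = []
    if var[0] > var[1]:
        picks.append(0)
    for i in range(1, W - 1):
        if var[i] > var[i - 1] and var[i] > var[i + 1]:
            picks.append(i)
    if var[-1] > var[-2]:
        picks.append(W - 1)
    if not picks:  # monotone plateaued series
        warnings.warn("no local maxima in variability; uniform subsampling fallback")
        return np.arange(0, W, max(1, W // 10))
    return np.asarray(picks, dtype=int)


def _distances(points: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    name = {"l1": "cityblock", "correlation": "correlation", "cosine": "cosine"}[metric]
    return cdist(points, centroids, metric=name)


def _update_centroid(members: np.ndarray, metric: str) -> np.ndarray:
    if metric == "l1":
        return np.median(members, axis=0)
    if metric == "cosine":
        m = members.mean(axis=0)
        n = np.linalg.norm(m)
        return m if n == 0 else m / n
    # correlation: demean each member, then normalized mean
    demeaned = members - members.mean(axis=1, keepdims=True)
    m = demeaned.mean(axis=0)
    n = np.linalg.norm(m)
    return m if n == 0 else m / n


def _lloyd(
    points: np.ndarray,
    init: np.ndarray,
    metric: str,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, float]:
    centroids = init.copy()
    k = centroids.shape[0]
    labels = np.full(points.shape[0], -1)
    for _ in range(max_iter):
        D = _distances(points, centroids, metric)
        new_labels = D.argmin(axis=1)
        for c in range(k):  # re-seed empty clusters at the farthest point
            if not (new_labels == c).any():
                far = D.min(axis=1).argmax()
                centroids[c] = points[far]
                new_labels[far] = c
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = _update_centroid(points[labels == c], metric)
    D = _distances(points, centroids, metric)
    labels = D.argmin(axis=1)
    inertia = float(D[np.arange(points.shape[0]), labels].sum())
    return centroids, labels, inertia


def kmeans_fit(
    points: np.ndarray,
    k: int,
    metric: str = "l1",
    n_replicates: int = 5,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd-style k-means under an L1, correlation, or cosine metric.

    Centroid updates: coordinate-wise median (L1) or normalized mean
    (correlation/cosine). With ``init`` given, a single run starts from
    those centroids; otherwise the best of ``n_replicates`` random
    initializations (by total within-cluster distance) is returned.
    Returns ``(centroids, labels, inertia)``.
    """
    points = np.asarray(points, dtype=float)
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if k > points.shape[0]:
        raise ValueError("k exceeds the number of points")
    if init is not None:
        return _lloyd(points, np.asarray(init, dtype=float), metric)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_replicates):
        result = _lloyd(points, _kmeanspp_init(points, k, metric, rng), metric)
        if best is None or result[2] < best[2]:
            best = result
    return best


def _kmeanspp_init(
    points: np.ndarray, k: int, metric: str, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding: new centers sampled proportionally to the distance
    to the nearest already-chosen center, under the working metric."""
    n = points.shape[0]
    centers = [points[rng.integers(n)]]
    d = _distances(points, np.asarray(centers), metric)[:, 0]
    for _ in range(1, k):
        total = d.sum()
        if total <= 0:
            centers.append(points[rng.integers(n)])
            continue
        centers.append(points[rng.choice(n, p=d / total)])
        d = np.minimum(
            d, _distances(points, centers[-1][None, :], metric)[:, 0]
        )
    return np.asarray(centers)


def cluster_validity_ratio(
    points: np.ndarray, centroids: np.ndarray, labels: np.ndarray, metric: str
) -> float:
    """Within/between cluster-distance ratio.

    Within: mean distance of each point to its own centroid. Between: mean
    distance of each point to the centroids of the other clusters, which
    keeps both terms on the same (point-level) scale.
    """
    D = _distances(points, centroids, metric)
    n = points.shape[0]
    k = centroids.shape[0]
    if k < 2:
        return np.inf
    own = D[np.arange(n), labels]
    mask = np.ones_like(D, dtype=bool)
    mask[np.arange(n), labels] = False
    between = D[mask].mean()
    return float(own.mean() / between) if between > 0 else np.inf


def choose_k_elbow(
    points: np.ndarray,
    k_range: range | list[int] = range(2, 11),
    metric: str = "l1",
    n_replicates: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Elbow criterion on the within/between cluster-distance ratio.

    The ratio curve decreases with k; the chosen k is the sharpest bend,
    the maximizer of the discrete second difference over interior k. A
    non-decreasing curve (no structure) returns the smallest k with a
    warning. Returns ``(k_star, ratio_curve)``.
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k range must span at least 3 values")
    ratios = np.empty(len(ks))
    for i, k in enumerate(ks):
        centroids, labels, _ = kmeans_fit(
            points, k, metric=metric, n_replicates=n_replicates, seed=seed + i
        )
        ratios[i] = cluster_validity_ratio(points, centroids, labels, metric)
    second_diff = ratios[:-2] - 2 * ratios[1:-1] + ratios[2:]
    span = ratios.max() - ratios.min()
    no_bend = (
        not np.isfinite(ratios).all()
        or np.all(np.diff(ratios) >= 0)
        or second_diff.max() < 0.1 * span
    )
    if no_bend:
        warnings.warn(
            "validity-ratio curve shows no distinct bend (no clear cluster "
            "structure); returning smallest k"
        )
        return ks[0], ratios
    return ks[1 + int(np.argmax(second_diff))], ratios


def cluster_states(
    dfnc_by_subject: dict[str, DynFNC],
    k: int,
    metric: str = "l1",
    n_replicates: int = 5,
    seed: int = 0,
    groups: dict[str, str] | None = None,
    max_exemplars: int = 20000,
) -> StateModel:
    """Two-stage clustering of all subjects' windowed connectivity.

    Stage 1: k-means on pooled subject exemplars (best of replicates).
    Stage 2: a single k-means run over every window of every subject,
    initialized at the stage-1 centroids. Group-specific centroids are the
    per-group means of windows under the global assignment.
    """
    subjects = list(dfnc_by_subject)
    exemplars = []
    for s in subjects:
        vecs = dfnc_by_subject[s].edge_vectors()
        exemplars.append(vecs[select_exemplars(dfnc_by_subject[s])])
    pooled = np.concatenate(exemplars, axis=0)
    if pooled.shape[0] > max_exemplars:
        rng = np.random.default_rng(seed)
        pooled = pooled[rng.choice(pooled.shape[0], max_exemplars, replace=False)]
    if pooled.shape[0] < k:
        raise ValueError("fewer pooled exemplars than states")
    seed_centroids, _, _ = kmeans_fit(
        pooled, k, metric=metric, n_replicates=n_replicates, seed=seed
    )
    all_vecs = np.concatenate(
        [dfnc_by_subject[s].edge_vectors() for s in subjects], axis=0
    )
    centroids, labels, inertia = kmeans_fit(
        all_vecs, k, metric=metric, init=seed_centroids
    )
    # guard against a poor exemplar-stage optimum: the final model is never
    # worse (in total within-cluster distance) than random restarts
    alt = kmeans_fit(
        all_vecs, k, metric=metric, n_replicates=n_replicates, seed=seed + 1
    )
    if alt[2] < inertia:
        centroids, labels, inertia = alt
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        warnings.warn("degenerate state: at least one state received no windows")
    assignments: dict[str, np.ndarray] = {}
    start = 0
    for s in subjects:
        W = dfnc_by_subject[s].W
        assignments[s] = labels[start : start + W]
        start += W
    group_centroids: dict[str, np.ndarray] = {}
    if groups is not None:
        for g in sorted(set(groups.values())):
            vecs = np.concatenate(
                [
                    dfnc_by_subject[s].edge_vectors()
                    for s in subjects
                    if groups[s] == g
                ],
                axis=0,
            )
            labs = np.concatenate(
                [assignments[s] for s in subjects if groups[s] == g]
            )
            gc = np.full((k, vecs.shape[1]), np.nan)
            for c in range(k):
                if (labs == c).any():
                    gc[c] = vecs[labs == c].mean(axis=0)
            group_centroids[g] = gc
    return StateModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        counts=counts,
        percentages=100.0 * counts / counts.sum(),
        metric=metric,
        group_centroids=group_centroids,
    )


def subject_summary(
    labels: np.ndarray, k: int, vectors: np.ndarray | None = None
) -> SubjectStateSummary:
    """Per-subject state statistics from a window-ordered label sequence.

    Transitions count label changes between consecutive windows; entries
    into state s count windows whose label is s while the previous label is
    not. When ``vectors`` is given, per-state subject centroids (means of
    the subject's member windows) are included.
    """
    labels = np.asarray(labels, dtype=int)
    W = labels.size
    dwell = np.bincount(labels, minlength=k) / W
    visited = dwell > 0
    n_trans = int((labels[1:] != labels[:-1]).sum())
    entries = np.zeros(k, dtype=int)
    for s in range(k):
        entries[s] = int(((labels[1:] == s) & (labels[:-1] != s)).sum())
    centroids: dict[int, np.ndarray] = {}
    if vectors is not None:
        for s in range(k):
            if visited[s]:
                centroids[s] = vectors[labels == s].mean(axis=0)
    return SubjectStateSummary(
        centroids=centroids,
        visited=visited,
        dwell_fractions=dwell,
        n_transitions=n_trans,
        entries=entries,
    )
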