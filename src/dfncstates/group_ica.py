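"""Group spatial ICA with back-reconstruction of subject maps and timecourses.

Two-stage PCA reduction (subject-level then group-level on the stacked
reduced data) followed by natural-gradient Infomax ICA; decomposition
stability is assessed by repeating ICA from random starts and clustering
the resulting components (ICASSO-style). Subject-specific spatial maps and
timecourses are recovered by projecting the group model back through each
subject's PCA compression (GICA1).

Spatial ICA convention: the data matrix is voxels x time, sources are
spatial maps, and mixing columns are timecourses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "PcaReduction",
    "GroupDecomposition",
    "SubjectDecomposition",
    "subject_pca",
    "group_pca",
    "infomax_ica",
    "icasso_stability",
    "gica1_backreconstruct",
    "identify_icns",
]


@dataclass
class PcaReduction:
    """Retained principal directions of one subject's temporal dimension."""

    basis: np.ndarray  # (T, n_retained), orthonormal columns
    variance_explained: float
    n_retained: int


@dataclass
class GroupDecomposition:
    maps: np.ndarray  # (C, V) group spatial maps
    mixing: np.ndarray  # (C, C) mixing in the group-reduced space
    unmixing: np.ndarray  # (C, C)
    stability: np.ndarray | None = None  # (C,) per-component index in [0, 1]


@dataclass
class SubjectDecomposition:
    maps: np.ndarray  # (C, V)
    timecourses: np.ndarray  # (T, C)


def subject_pca(
    X: np.ndarray, n_components: int
) -> tuple[PcaReduction, np.ndarray]:
    """Reduce one subject's voxel-by-time matrix along the time dimension.

    Returns the reduction (temporal basis + variance fraction) and the
    reduced data ``Y = X @ basis`` of shape (V, n_components).
    """
    X = np.asarray(X, dtype=float)
    V, T = X.shape
    if n_components > min(V, T):
        raise ValueError("n_components exceeds data rank bound")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    kept = float((s[:n_components] ** 2).sum())
    basis = Vt[:n_components].T  # (T, n)
    reduced = X @ basis
    return (
        PcaReduction(
            basis=basis,
            variance_explained=1.0 if total == 0 else kept / total,
            n_retained=n_components,
        ),
        reduced,
    )


def group_pca(
    reduced_subjects: list[np.ndarray], C: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Group-level reduction of subject-reduced data stacked along columns.

    Returns the group-reduced matrix ``Z`` (V, C) and, per subject, the
    block ``G_i`` (n_i, C) of the stacking projection, needed for GICA1
    back-reconstruction. Computed by exact eigendecomposition (SVD); an EM
    accelerator would be a memory optimization, not a different estimator.
    """
    Y = np.concatenate(reduced_subjects, axis=1)
    if C > min(Y.shape):
        raise ValueError("C exceeds the rank bound of the stacked data")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    Z = U[:, :C] * s[:C]
    G = Vt[:C].T  # (sum n_i, C), orthonormal columns
    blocks = []
    start = 0
    for R in reduced_subjects:
        n_i = R.shape[1]
        blocks.append(G[start : start + n_i])
        start += n_i
    return Z, blocks


def _whiten(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Whiten rows of a C x N matrix; returns (white data, sphering, mean)."""
    mu = Z.mean(axis=1, keepdims=True)
    Zc = Z - mu
    cov = Zc @ Zc.T / Zc.shape[1]
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 1e-12, None)
    sphering = (v / np.sqrt(w)) @ v.T
    return sphering @ Zc, sphering, mu


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """Project W onto the nearest orthogonal matrix (W W^T)^(-1/2) W."""
    w, v = np.linalg.eigh(W @ W.T)
    return (v / np.sqrt(np.clip(w, 1e-12, None))) @ v.T @ W


def _orient_maps(maps: np.ndarray) -> np.ndarray:
    """Sign convention: each map's maximum-magnitude element is positive."""
    out = maps.copy()
    for i in range(out.shape[0]):
        peak = out[i, np.argmax(np.abs(out[i]))]
        if peak < 0:
            out[i] = -out[i]
    return out


def infomax_ica(
    Z: np.ndarray,
    C: int | None = None,
    seed: int = 0,
    extended: bool = False,
    max_iter: int = 512,
    tol: float = 1e-12,
) -> GroupDecomposition:
    """Natural-gradient Infomax ICA on internally whitened data.

    ``Z`` is a C x N matrix (rows mixtures, columns samples). The default
    logistic nonlinearity suits super-Gaussian sources (sparse spatial
    maps); ``extended=True`` adds a kurtosis-sign switch so sub-Gaussian
    sources (e.g. uniform) separate as well. The converged
    unmixing matrix is symmetrically decorrelated: on whitened data the
    true unmixing is orthogonal, and projecting onto the orthogonal group
    removes residual correlation between recovered sources.
    """
    from mne.preprocessing import infomax as _mne_infomax

    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if C is not None and C != Z.shape[0]:
        raise ValueError("C must match the row count of the reduced data")
    C_eff = Z.shape[0]
    X, sphering, _ = _whiten(Z)
    if C_eff == 1:
        maps = _orient_maps(X.copy())
        one = np.ones((1, 1))
        return GroupDecomposition(maps=maps, mixing=one, unmixing=one)
    W = _mne_infomax(
        X.T,
        extended=extended,
        max_iter=max_iter,
        w_change=tol,
        rng=np.random.RandomState(seed),
        verbose="error",
    )
    W = _sym_decorrelate(W)
    raw_maps = W @ X
    # sign convention applied to W rows so maps and mixing stay consistent
    signs = np.sign(
        raw_maps[np.arange(C_eff), np.argmax(np.abs(raw_maps), axis=1)]
    )
    signs[signs == 0] = 1.0
    W = signs[:, None] * W
    maps = signs[:, None] * raw_maps
    # unmixing/mixing expressed w.r.t. the original (unwhitened) rows
    W_full = W @ sphering
    return GroupDecomposition(
        maps=maps, mixing=np.linalg.inv(W_full), unmixing=W_full
    )


def icasso_stability(
    Z: np.ndarray,
    C: int | None = None,
    n_runs: int = 20,
    seed: int = 0,
    seeds: list[int] | None = None,
    **ica_kwargs,
) -> GroupDecomposition:
    """Repeat Infomax from different starts and cluster the components.

    Components from all runs are clustered by absolute Pearson correlation
    (average linkage, cut at C clusters); each cluster's centrotype (the
    member most similar to the rest of its cluster) is the final map. The
    per-cluster stability index is the average within-cluster similarity
    minus the average similarity to components outside the cluster.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    C_eff = Z.shape[0] if C is None else C
    run_seeds = (
        list(seeds)
        if seeds is not None
        else [seed + 1000 * r for r in range(n_runs)]
    )
    runs = [infomax_ica(Z, seed=s, **ica_kwargs) for s in run_seeds[:n_runs]]
    all_maps = np.concatenate([r.maps for r in runs], axis=0)
    M = all_maps.shape[0]
    centered = all_maps - all_maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    sim = np.abs((centered / norms[:, None]) @ (centered / norms[:, None]).T)
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(link, t=C_eff, criterion="maxclust")
    n_found = len(np.unique(labels))
    if n_found < C_eff:
        warnings.warn(
            f"degenerate ICASSO clustering: {n_found} clusters < C={C_eff}"
        )
    maps = np.empty((n_found, Z.shape[1]))
    stability = np.empty(n_found)
    for ci, lab in enumerate(np.unique(labels)):
        members = np.where(labels == lab)[0]
        others = np.where(labels != lab)[0]
        sub = sim[np.ix_(members, members)]
        if members.size > 1:
            within = (sub.sum() - members.size) / (
                members.size * (members.size - 1)
            )
        else:
            within = 1.0
        between = (
            sim[np.ix_(members, others)].mean() if others.size else 0.0
        )
        stability[ci] = within - between
        # centrotype: member with the highest total similarity to its cluster
        centro = members[np.argmax(sub.sum(axis=1))]
        maps[ci] = all_maps[centro]
    order = np.argsort(stability)[::-1]
    best_run = runs[0]
    return GroupDecomposition(
        maps=_orient_maps(maps[order]),
        mixing=best_run.mixing,
        unmixing=best_run.unmixing,
        stability=stability[order],
    )


def gica1_backreconstruct(
    subject_reduced: np.ndarray,
    subject_pca_basis: np.ndarray,
    group_block: np.ndarray,
    group_model: GroupDecomposition,
) -> SubjectDecomposition:
    """GICA1: subject maps and timecourses via PCA compression + projection.

    With subject reduction ``Y_i = X_i F_i`` (``F_i`` the T x L temporal
    basis), group stacking block ``G_i`` (L x C) and group mixing ``A``:
    subject timecourses are ``TC_i = F_i G_i A`` and subject maps are
    ``SM_i = W G_i^T Y_i^T`` with ``W`` the group unmixing.
    """
    F = np.asarray(subject_pca_basis, dtype=float)  # (T, L)
    G = np.asarray(group_block, dtype=float)  # (L, C)
    Y = np.asarray(subject_reduced, dtype=float)  # (V, L)
    if F.shape[1] != G.shape[0] or Y.shape[1] != G.shape[0]:
        raise ValueError("inconsistent subject/group dimensions")
    A = group_model.mixing
    W = group_model.unmixing
    tcs = F @ G @ A  # (T, C)
    maps = W @ G.T @ Y.T  # (C, V)
    return SubjectDecomposition(maps=maps, timecourses=tcs)


def identify_icns(
    timecourses: np.ndarray,
    TR: float,
    low_freq_hz: float = 0.10,
    min_low_fraction: float | None = 0.5,
    min_dynamic_range: float | None = None,
    keep_list: list[int] | None = None,
) -> list[int]:
    """Select intrinsic-connectivity-network components by spectral criteria.

    Components are scored by the fraction of spectral power below
    ``low_freq_hz`` and by spectral dynamic range (peak minus minimum of the
    amplitude spectrum). Thresholds set to None disable that criterion. The
    result is intersected with an optional user keep-list (anatomical
    curation is inherently manual and enters through that list).
    """
    from scipy.signal import periodogram

    tcs = np.atleast_2d(np.asarray(timecourses, dtype=float))  # (T, C)
    freqs, pxx = periodogram(tcs, fs=1.0 / TR, axis=0)
    total = pxx.sum(axis=0)
    total[total == 0] = 1.0
    low_frac = pxx[freqs <= low_freq_hz].sum(axis=0) / total
    amp = np.sqrt(pxx)
    dyn_range = amp.max(axis=0) - amp.min(axis=0)
    C = tcs.shape[1]
    selected = np.ones(C, dtype=bool)
    if min_low_fraction is not None:
        selected &= low_frac >= min_low_fraction
    if min_dynamic_range is not None:
        selected &= dyn_range >= min_dynamic_range
    idx = [c for c in range(C) if selected[c]]
    if keep_list is not None:
        idx = [c for c in idx if c in set(keep_list)]
    if not idx:
        warnings.warn("no components passed the ICN selection criteria")
    return idx
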