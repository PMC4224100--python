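"""Sliding-window regularized dynamic connectivity (dFNC) estimation.

Per subject: a Tukey-tapered window (default width 22 TRs, step 1 TR)
slides along the component timecourses; within each window an L1-penalized
precision matrix (graphical lasso) is fitted to the taper-weighted sample
covariance, the covariance implied by that sparse precision is normalized
to a correlation matrix, and the Fisher-z slices are stacked into a
C x C x W array. The penalty is selected per subject by cross-validated
held-out log-likelihood over windowed covariances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows as sig_windows
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.exceptions import ConvergenceWarning

from dfncstates.preprocess import SubjectTimecourses
from dfncstates.static_fnc import fisher_z

__all__ = [
    "WindowSpec",
    "DynFNC",
    "GlassoFit",
    "make_taper",
    "window_starts",
    "windowed_cov",
    "glasso",
    "select_lambda",
    "compute_dfnc",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = np.logspace(np.log10(0.01), np.log10(1.0), 10)


@dataclass
class WindowSpec:
    """Sliding-window settings: width/step in TR units, Tukey taper shape."""

    width: int = 22
    step: int = 1
    taper: str = "tukey"
    taper_param: float = 0.5

    def __post_init__(self) -> None:
        if self.width < 3:
            raise ValueError("window width must be >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.taper == "tukey" and not (0.0 <= self.taper_param <= 1.0):
            raise ValueError("Tukey shape parameter must lie in [0, 1]")


@dataclass
class DynFNC:
    """Per-subject stack of windowed Fisher-z connectivity matrices."""

    values: np.ndarray  # (C, C, W)
    window_starts: np.ndarray
    lam: float
    spec: WindowSpec

    @property
    def C(self) -> int:
        return self.values.shape[0]

    @property
    def W(self) -> int:
        return self.values.shape[2]

    def edge_vectors(self) -> np.ndarray:
        """(W, C*(C-1)/2) array of vectorized upper triangles."""
        iu = np.triu_indices(self.C, k=1)
        return self.values[iu[0], iu[1], :].T


@dataclass
class GlassoFit:
    precision: np.ndarray
    covariance: np.ndarray
    lam: float
    objective: float


def make_taper(spec: WindowSpec) -> np.ndarray:
    """Tapered-cosine (Tukey) weights; alpha=0 is rectangular, alpha=1 Hann."""
    if spec.taper == "rect":
        return np.ones(spec.width)
    if spec.taper != "tukey":
        raise ValueError(f"unknown taper '{spec.taper}'")
    return sig_windows.tukey(spec.width, alpha=spec.taper_param, sym=True)


def window_starts(T: int, spec: WindowSpec) -> np.ndarray:
    """Start indices 0, step, 2*step, ... while start + width <= T."""
    if T < spec.width:
        raise ValueError("timecourse shorter than the window width")
    n = (T - spec.width) // spec.step + 1
    return np.arange(n) * spec.step


def windowed_cov(
    values: np.ndarray, start: int, spec: WindowSpec, weights: np.ndarray | None = None
) -> np.ndarray:
    """Taper-weighted sample covariance of one window.

    Samples are demeaned by the weighted mean and the weighted outer-product
    sum is normalized by the sum of weights.
    """
    w = make_taper(spec) if weights is None else np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("taper weights sum to zero")
    seg = values[start : start + spec.width]
    if seg.shape[0] != spec.width:
        raise ValueError("window extends past the end of the data")
    wsum = w.sum()
    mu = (w[:, None] * seg).sum(axis=0) / wsum
    D = seg - mu
    return (D * w[:, None]).T @ D / wsum


def _glasso_objective(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(logdet - np.trace(S @ theta) - lam * off)


def glasso(S: np.ndarray, lam: float, max_iter: int = 200, tol: float = 1e-4) -> GlassoFit:
    """L1-penalized precision estimation (graphical lasso).

    Maximizes ``log det T - tr(S T) - lam * sum_{i!=j} |T_ij|``. At lam = 0
    the solution is the exact inverse of S, computed directly. For lam > 0
    the problem is solved on the correlation scale (variances divided out,
    making the penalty scale-free) and mapped back; short windows produce
    ill-conditioned covariances, and a small diagonal ridge is added as a
    fallback before giving up.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    S = (S + S.T) / 2.0
    if lam == 0:
        theta = np.linalg.inv(S)
        return GlassoFit(
            precision=(theta + theta.T) / 2.0,
            covariance=S.copy(),
            lam=0.0,
            objective=_glasso_objective(S, theta, 0.0),
        )
    d = np.sqrt(np.diag(S))
    if (d <= 0).any():
        raise ValueError("S has non-positive diagonal entries")
    R = S / np.outer(d, d)
    last_err: Exception | None = None
    for ridge in (0.0, 1e-3, 1e-2):
        Rr = R + ridge * np.eye(R.shape[0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                cov_r, theta_r = _sk_glasso(
                    Rr, alpha=lam, max_iter=max_iter, tol=tol
                )
            break
        except FloatingPointError as err:
            last_err = err
    else:
        raise RuntimeError(
            f"graphical lasso failed to converge at lambda={lam}: {last_err}"
        ) from last_err
    theta = (theta_r + theta_r.T) / 2.0 / np.outer(d, d)
    cov = (cov_r + cov_r.T) / 2.0 * np.outer(d, d)
    return GlassoFit(
        precision=theta,
        covariance=cov,
        lam=float(lam),
        objective=_glasso_objective(S, theta, lam),
    )


def _heldout_score(theta: np.ndarray, S_test: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S_test @ theta))


def select_lambda(
    window_covs: list[np.ndarray],
    grid: np.ndarray | None = None,
    n_folds: int = 5,
    rule: str = "max",
) -> float:
    """Cross-validated penalty selection over a subject's windowed covariances.

    Folds are contiguous blocks of windows (respecting serial dependence).
    For each lambda, the precision is fitted on the pooled training
    covariance and scored on each held-out window by the Gaussian
    log-likelihood ``log det T - tr(S_test T)``.

    ``rule='max'`` returns the lambda with the best mean held-out score
    (ties going to the smaller lambda); ``rule='1se'`` returns the largest
    lambda whose mean score lies within one standard error of the best — the
    parsimony rule to use when the sparsity pattern itself is of interest,
    since the held-out likelihood is typically flat near its maximum.
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    grid = np.sort(grid)
    if rule not in ("max", "1se"):
        raise ValueError("rule must be 'max' or '1se'")
    W = len(window_covs)
    n_folds = min(n_folds, W)
    if n_folds < 2:
        raise ValueError("need at least 2 folds of windows")
    bounds = np.linspace(0, W, n_folds + 1).astype(int)
    folds = [np.arange(bounds[i], bounds[i + 1]) for i in range(n_folds)]
    covs = np.stack(window_covs)
    scores = np.full(grid.size, -np.inf)
    ses = np.full(grid.size, np.inf)
    for gi, lam in enumerate(grid):
        fold_scores = []
        ok = True
        for test_idx in folds:
            train_mask = np.ones(W, dtype=bool)
            train_mask[test_idx] = False
            S_train = covs[train_mask].mean(axis=0)
            try:
                fit = glasso(S_train, lam)
            except (RuntimeError, np.linalg.LinAlgError):
                ok = False
                break
            fold_scores.append(
                np.mean([_heldout_score(fit.precision, covs[t]) for t in test_idx])
            )
        if ok:
            scores[gi] = np.mean(fold_scores)
            if len(fold_scores) > 1:
                ses[gi] = np.std(fold_scores, ddof=1) / np.sqrt(len(fold_scores))
    if not np.isfinite(scores).any():
        raise RuntimeError("every graphical-lasso fit failed on the grid")
    best = np.flatnonzero(scores == scores.max())[0]  # ties -> smaller lambda
    if rule == "1se" and np.isfinite(ses[best]):
        ok = np.flatnonzero(scores >= scores[best] - ses[best])
        return float(grid[ok.max()])
    return float(grid[best])


def compute_dfnc(
    tc: SubjectTimecourses, spec: WindowSpec | None = None, lam: float = 0.0
) -> DynFNC:
    """Windowed regularized connectivity stack for one subject.

    Per window: taper-weighted covariance -> graphical lasso at ``lam`` ->
    covariance implied by the sparse precision -> correlation -> Fisher z
    (diagonal set to 0 on the z scale).
    """
    spec = spec or WindowSpec()
    starts = window_starts(tc.T, spec)
    weights = make_taper(spec)
    C = tc.C
    out = np.empty((C, C, starts.size))
    for wi, s in enumerate(starts):
        Sw = windowed_cov(tc.values, int(s), spec, weights)
        if lam == 0:
            cov_est = Sw
        else:
            cov_est = glasso(Sw, lam).covariance
        d = np.sqrt(np.diag(cov_est))
        d[d == 0] = 1.0
        r = cov_est / np.outer(d, d)
        z = fisher_z(r)
        np.fill_diagonal(z, 0.0)
        out[:, :, wi] = (z + z.T) / 2.0
    return DynFNC(values=out, window_starts=starts, lam=float(lam), spec=spec)
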