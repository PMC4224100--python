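"""Static functional network connectivity (FNC) and group contrasts.

Static FNC is the C x C correlation matrix of a subject's post-processed
component timecourses. Averaging and testing happen on the Fisher-z scale
(z = atanh r); network-group (NG) aggregation averages component-pair
connectivity within and between functional families of components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dfncstates.preprocess import SubjectTimecourses

__all__ = [
    "FncMatrix",
    "fisher_z",
    "inverse_fisher_z",
    "static_fnc",
    "group_mean_fnc",
    "ng_average",
    "static_group_contrast",
]

_R_CLIP = 1.0 - 1e-12


@dataclass
class FncMatrix:
    """Symmetric C x C connectivity matrix on the r or Fisher-z scale."""

    values: np.ndarray
    scale: str = "r"  # "r" or "z"
    component_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("r", "z"):
            raise ValueError("scale must be 'r' or 'z'")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("FNC matrix must be square")
        if not self.component_ids:
            self.component_ids = [
                f"IC{c + 1}" for c in range(self.values.shape[0])
            ]

    @property
    def C(self) -> int:
        return self.values.shape[0]

    def to_z(self) -> "FncMatrix":
        if self.scale == "z":
            return self
        z = np.arctanh(np.clip(self.values, -_R_CLIP, _R_CLIP))
        np.fill_diagonal(z, 0.0)
        return FncMatrix(z, scale="z", component_ids=list(self.component_ids))

    def to_r(self) -> "FncMatrix":
        if self.scale == "r":
            return self
        r = np.tanh(self.values)
        np.fill_diagonal(r, 1.0)
        return FncMatrix(r, scale="r", component_ids=list(self.component_ids))


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP))


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(np.asarray(z, dtype=float))


def static_fnc(tc: SubjectTimecourses, scale: str = "r") -> FncMatrix:
    """Pearson correlation matrix of the component timecourses over the run."""
    X = tc.values
    sd = X.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance components; entries set to NaN"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[flat, :] = np.nan
    r[:, flat] = np.nan
    np.fill_diagonal(r, 1.0)
    out = FncMatrix(r, scale="r", component_ids=list(tc.component_ids))
    return out.to_z() if scale == "z" else out


def group_mean_fnc(matrices: list[FncMatrix]) -> FncMatrix:
    """Subject-mean FNC: averaged on the Fisher-z scale, returned on r scale."""
    scales = {m.scale for m in matrices}
    if len(scales) > 1:
        raise ValueError("cannot mix r- and z-scale matrices")
    dims = {m.C for m in matrices}
    if len(dims) > 1:
        raise ValueError("matrices must share dimensions")
    zs = np.stack([m.to_z().values for m in matrices])
    mean_z = zs.mean(axis=0)
    r = np.tanh(mean_z)
    np.fill_diagonal(r, 1.0)
    return FncMatrix(r, scale="r", component_ids=list(matrices[0].component_ids))


def ng_average(fnc: FncMatrix, partition: dict[str, list[int]]) -> pd.DataFrame:
    """Average connectivity within and between network groups (NGs).

    Off-diagonal NG entries average all between-group component pairs; the
    diagonal averages unordered within-group pairs, excluding the matrix
    diagonal. Singleton groups have no within-group pairs: NaN, flagged by
    a warning.
    """
    C = fnc.C
    covered = sorted(i for comps in partition.values() for i in comps)
    if covered != sorted(set(covered)) or set(covered) != set(range(C)):
        raise ValueError("partition must cover every component exactly once")
    groups = list(partition)
    M = fnc.values
    out = np.full((len(groups), len(groups)), np.nan)
    for a, ga in enumerate(groups):
        ia = partition[ga]
        for b, gb in enumerate(groups):
            ib = partition[gb]
            if a == b:
                if len(ia) < 2:
                    warnings.warn(f"singleton NG '{ga}': within-average undefined")
                    continue
                vals = [M[i, j] for x, i in enumerate(ia) for j in ia[x + 1 :]]
                out[a, b] = np.mean(vals)
            else:
                out[a, b] = np.mean([M[i, j] for i in ia for j in ib])
    return pd.DataFrame(out, index=groups, columns=groups)


def _welch_matrix(
    za: np.ndarray, zb: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Entrywise Welch t-test between two stacks of z matrices (n, C, C)."""
    res = stats.ttest_ind(za, zb, axis=0, equal_var=False)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN p-values stay NaN and are not counted."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def static_group_contrast(
    matrices_by_group: dict[str, list[FncMatrix]],
    pair: tuple[str, str],
    level: str = "edge",
    partition: dict[str, list[int]] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Two-sample contrast of static FNC between a pair of groups.

    Welch t-tests per entry on the Fisher-z scale with Benjamini-Hochberg
    correction across the family of tested entries (unique edges, or unique
    NG pairs when ``level='ng'``).
    """
    ga, gb = pair
    for g in pair:
        if len(matrices_by_group.get(g, [])) < 2:
            raise ValueError(f"group '{g}' needs at least 2 subjects")
    if level == "ng":
        if partition is None:
            raise ValueError("NG-level contrast requires a partition")
        stack_a = np.stack(
            [ng_average(m.to_z(), partition).values for m in matrices_by_group[ga]]
        )
        stack_b = np.stack(
            [ng_average(m.to_z(), partition).values for m in matrices_by_group[gb]]
        )
        names = list(partition)
        include_diag = True
    elif level == "edge":
        stack_a = np.stack([m.to_z().values for m in matrices_by_group[ga]])
        stack_b = np.stack([m.to_z().values for m in matrices_by_group[gb]])
        names = list(matrices_by_group[ga][0].component_ids)
        include_diag = False
    else:
        raise ValueError("level must be 'edge' or 'ng'")
    t, p = _welch_matrix(stack_a, stack_b)
    t, p = np.atleast_2d(t), np.atleast_2d(p)
    n = t.shape[0]
    iu = np.triu_indices(n, k=0 if include_diag else 1)
    q_flat = bh_qvalues(p[iu])
    q = np.full_like(p, np.nan)
    q[iu] = q_flat
    q[(iu[1], iu[0])] = q_flat  # symmetrize
    return {
        "pair": pair,
        "level": level,
        "names": names,
        "t": t,
        "p": p,
        "q": q,
        "significant": q < alpha,
    }
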