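"""Group statistics: edgewise state contrasts with FDR control, transition
comparisons, and cohort demographic tests.

State contrasts compare subject-specific state centroids (Fisher-z) between
two groups with Welch t-tests per edge; Benjamini-Hochberg correction is
applied within each state-by-pair family. Demographic tests reproduce the
standard cohort table checks: a one-way ANOVA on age computable from group
summary statistics (n, mean, SD) and a Pearson chi-square on the sex-by-
group contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from dfncstates.static_fnc import bh_qvalues
from dfncstates.states import SubjectStateSummary

__all__ = [
    "GroupContrast",
    "DemographicsTable",
    "state_contrast",
    "transition_contrast",
    "demographic_tests",
    "covariate_correlation",
]


@dataclass
class GroupContrast:
    state: int
    pair: tuple[str, str]
    t: np.ndarray  # (C, C) symmetric
    p: np.ndarray
    q: np.ndarray
    n_a: int
    n_b: int

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.q < alpha


@dataclass
class DemographicsTable:
    groups: list[str]
    n: np.ndarray
    age_mean: np.ndarray
    age_sd: np.ndarray
    females: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.age_mean = np.asarray(self.age_mean, dtype=float)
        self.age_sd = np.asarray(self.age_sd, dtype=float)
        self.females = np.asarray(self.females, dtype=int)
        if (self.n <= 0).any():
            raise ValueError("group sizes must be positive")
        if (self.females > self.n).any():
            raise ValueError("female count cannot exceed group size")


def _vec_to_matrix(vec: np.ndarray, C: int) -> np.ndarray:
    m = np.full((C, C), np.nan)
    iu = np.triu_indices(C, k=1)
    m[iu] = vec
    m[(iu[1], iu[0])] = vec
    return m


def state_contrast(
    centroids_by_group: dict[str, np.ndarray],
    state: int,
    pair: tuple[str, str],
    C: int,
    alpha: float = 0.05,
) -> GroupContrast | None:
    """Edgewise Welch t-test between two groups' subject state centroids.

    ``centroids_by_group[g]`` is an (n_subjects, n_edges) array of Fisher-z
    centroid vectors for subjects of group ``g`` that visited the state;
    subjects that never visited contribute no row. Returns None (with a
    warning) when either group has fewer than 2 visitors.
    """
    ga, gb = pair
    za = np.atleast_2d(centroids_by_group.get(ga, np.empty((0, 0))))
    zb = np.atleast_2d(centroids_by_group.get(gb, np.empty((0, 0))))
    if za.shape[0] < 2 or zb.shape[0] < 2:
        warnings.warn(
            f"state {state}, pair {pair}: fewer than 2 visitors per group; skipped"
        )
        return None
    res = stats.ttest_ind(za, zb, axis=0, equal_var=False)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    q = bh_qvalues(p)
    return GroupContrast(
        state=state,
        pair=pair,
        t=_vec_to_matrix(t, C),
        p=_vec_to_matrix(p, C),
        q=_vec_to_matrix(q, C),
        n_a=za.shape[0],
        n_b=zb.shape[0],
    )


def transition_contrast(
    summaries_by_group: dict[str, list[SubjectStateSummary]],
    pair: tuple[str, str],
    k: int,
) -> dict:
    """Two-sample tests on per-state entry counts and total transitions.

    Welch t-tests per state on entry counts, BH-corrected across states;
    plus one test on the total transition count. States with all-zero
    counts in both groups are skipped (NaN).
    """
    ga, gb = pair
    ea = np.array([s.entries for s in summaries_by_group[ga]], dtype=float)
    eb = np.array([s.entries for s in summaries_by_group[gb]], dtype=float)
    t = np.full(k, np.nan)
    p = np.full(k, np.nan)
    for s in range(k):
        if ea[:, s].any() or eb[:, s].any():
            res = stats.ttest_ind(ea[:, s], eb[:, s], equal_var=False)
            t[s], p[s] = res.statistic, res.pvalue
    q = bh_qvalues(p)
    ta = np.array([s.n_transitions for s in summaries_by_group[ga]], dtype=float)
    tb = np.array([s.n_transitions for s in summaries_by_group[gb]], dtype=float)
    total = stats.ttest_ind(ta, tb, equal_var=False)
    return {
        "pair": pair,
        "per_state_t": t,
        "per_state_p": p,
        "per_state_q": q,
        "total_t": float(total.statistic),
        "total_p": float(total.pvalue),
    }


def anova_from_summaries(
    n: np.ndarray, mean: np.ndarray, sd: np.ndarray
) -> tuple[float, float, tuple[int, int]]:
    """One-way ANOVA F from per-group n, mean, and SD.

    Between-group SS uses the size-weighted grand mean; within-group SS is
    ``sum (n_g - 1) sd_g^2``. Returns (F, p, (df_between, df_within)).
    """
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if (n < 2).any():
        raise ValueError("each group needs n >= 2 for the ANOVA")
    grand = (n * mean).sum() / n.sum()
    df_b = len(n) - 1
    df_w = int(n.sum()) - len(n)
    ss_b = (n * (mean - grand) ** 2).sum()
    ss_w = ((n - 1) * sd**2).sum()
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p, (df_b, df_w)


def demographic_tests(table: DemographicsTable) -> dict:
    """Age ANOVA (from summaries) and sex chi-square (Pearson, no continuity
    correction) for a multi-group cohort table."""
    if len(table.groups) < 2:
        raise ValueError("need at least 2 groups")
    F, p_age, (df_b, df_w) = anova_from_summaries(
        table.n, table.age_mean, table.age_sd
    )
    contingency = np.vstack([table.females, table.n - table.females])
    chi2, p_sex, df_sex, _ = stats.chi2_contingency(contingency, correction=False)
    return {
        "age_F": F,
        "age_p": p_age,
        "age_df": (df_b, df_w),
        "sex_chi2": float(chi2),
        "sex_p": float(p_sex),
        "sex_df": int(df_sex),
    }


def covariate_correlation(
    values: np.ndarray, covariate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each connectivity column with a subject covariate.

    Generic hook for symptom-score analyses: ``values`` is (n_subjects,
    n_edges), ``covariate`` length n_subjects. Returns (r, p) per edge.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cov = np.asarray(covariate, dtype=float)
    r = np.empty(values.shape[1])
    p = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        r[j], p[j] = stats.pearsonr(values[:, j], cov)
    return r, p
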