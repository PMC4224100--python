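"""Synthetic multi-group cohorts of state-switching component timecourses.

Each subject's component signals follow a Markov chain over ``k`` latent
covariance regimes: at every timepoint the sample is drawn from a zero-mean
multivariate Gaussian whose covariance is the active state's (optionally
group-perturbed) correlation matrix. On top of the clean signal the
generator layers the artifacts the post-processing stage is designed to
remove: polynomial scanner drift, motion-coupled nuisance signal, and
sporadic heavy-tailed spikes. The planted truth (state sequence, state
covariances, group effects, mixing matrix) is returned alongside the data
so recovery can be scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StateCovSet",
    "GroupEffectSpec",
    "SubjectSimSpec",
    "SimTruth",
    "make_state_cov_set",
    "apply_group_effect",
    "simulate_subject",
    "simulate_cohort",
    "simulate_state_cohort",
    "mix_to_voxels",
    "write_cohort",
]

_EIG_FLOOR = 1e-4


@dataclass
class StateCovSet:
    """A set of k latent connectivity states as SPD correlation matrices."""

    k: int
    C: int
    covs: np.ndarray  # (k, C, C)

    def __post_init__(self) -> None:
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.shape != (self.k, self.C, self.C):
            raise ValueError("covs shape inconsistent with (k, C, C)")
        for m in self.covs:
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError("state covariance not symmetric")
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError("state covariance not positive definite")


@dataclass
class GroupEffectSpec:
    """Additive Fisher-z connectivity offsets on selected edges, per state.

    ``offsets[s]`` maps each edge ``(i, j)`` of ``edges`` to the z-offset
    applied in state ``s``; states absent from ``offsets`` are unperturbed.
    """

    group: str
    edges: list[tuple[int, int]] = field(default_factory=list)
    offsets: dict[int, np.ndarray] = field(default_factory=dict)

    def offsets_for_state(self, state: int) -> np.ndarray | None:
        if state in self.offsets:
            return np.asarray(self.offsets[state], dtype=float)
        return None


@dataclass
class SubjectSimSpec:
    """Per-subject simulation settings.

    Defaults reflect a 5-minute resting-state run: 210 acquired frames with
    the first 4 discarded (T = 206) at TR = 1.5 s.
    """

    T: int = 206
    TR: float = 1.5
    markov: np.ndarray | None = None
    drift: np.ndarray | None = None  # polynomial coeffs, ascending order <= 3
    spike_rate: float = 0.0  # expected spikes per 100 timepoints
    motion_coupling: float = 0.0
    seed: int = 0

    def validate(self, k: int) -> None:
        if self.T < 3:
            raise ValueError("T too small")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.markov is not None:
            P = np.asarray(self.markov, dtype=float)
            if P.shape != (k, k):
                raise ValueError("markov matrix shape must be (k, k)")
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("markov rows must sum to 1")
        if self.drift is not None and len(np.atleast_1d(self.drift)) > 4:
            raise ValueError("drift polynomial order must be <= 3")


@dataclass
class SimTruth:
    """Planted ground truth for one simulated subject."""

    state_sequence: np.ndarray  # (T,), values in 0..k-1
    states: StateCovSet
    effects: list[GroupEffectSpec]
    mixing: np.ndarray | None = None  # (V, C) when voxel data generated
    motion: np.ndarray | None = None  # (T, 6)
    spike_times: np.ndarray | None = None


def _factor_spd(
    C: int,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
    share: float = 0.0,
) -> np.ndarray:
    """Random SPD correlation matrix with factor structure L L' + D.

    The idiosyncratic variances D are kept small relative to the factors so
    states carry strong, sign-varying correlation structure — connectivity
    states are by definition patterns of pronounced coupling, not
    near-diagonal matrices. When ``base`` loadings are given, the state's
    loadings mix ``sqrt(share)`` of the base with ``sqrt(1-share)`` of a
    fresh draw, so ``share`` controls how similar states are to each other.
    """
    r = max(1, C // 3)
    L = rng.normal(size=(C, r))
    if base is not None and share > 0:
        L = np.sqrt(share) * base + np.sqrt(1.0 - share) * L
    d = rng.uniform(0.1, 0.4, size=C)
    cov = L @ L.T + np.diag(d)
    s = np.sqrt(np.diag(cov))
    return cov / np.outer(s, s)


def _offdiag_vec(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _matrix_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between the off-diagonal parts of two matrices."""
    va, vb = _offdiag_vec(a), _offdiag_vec(b)
    if va.std() == 0 or vb.std() == 0:
        return 0.0
    return float(np.corrcoef(va, vb)[0, 1])


def make_state_cov_set(
    k: int,
    C: int,
    separation: float = 0.5,
    seed: int = 0,
    max_retries: int = 2000,
) -> StateCovSet:
    """Draw k well-separated SPD correlation matrices.

    Separation is enforced as a ceiling of ``1 - separation`` on the pairwise
    Pearson correlation between the off-diagonal entries of distinct states.
    """
    if k < 1 or C < 2:
        raise ValueError("need k >= 1 and C >= 2")
    if not (0 < separation <= 1):
        raise ValueError("separation must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ceiling = 1.0 - separation
    # shared base loadings make low-separation states genuinely similar,
    # not merely unconstrained; the ceiling check below enforces the bound
    base = rng.normal(size=(C, max(1, C // 3)))
    covs: list[np.ndarray] = []
    tries = 0
    while len(covs) < k:
        cand = _factor_spd(C, rng, base=base, share=1.0 - separation)
        if all(abs(_matrix_correlation(cand, m)) <= ceiling for m in covs):
            covs.append(cand)
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"could not draw {k} states with separation {separation} "
                f"after {max_retries} tries"
            )
    return StateCovSet(k=k, C=C, covs=np.stack(covs))


def _nearest_spd_correlation(m: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and rescale to unit diagonal."""
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    w = np.clip(w, _EIG_FLOOR, None)
    out = (v * w) @ v.T
    s = np.sqrt(np.diag(out))
    return out / np.outer(s, s)


def apply_group_effect(
    cov: np.ndarray, effect: GroupEffectSpec | None, state: int
) -> np.ndarray:
    """Perturb a state correlation matrix by a group's edge offsets.

    Offsets are additive on the Fisher-z scale, applied symmetrically, and
    the result is re-projected to the nearest SPD correlation matrix.
    """
    if effect is None or not effect.edges:
        return cov
    off = effect.offsets_for_state(state)
    if off is None:
        return cov
    C = cov.shape[0]
    z = np.arctanh(np.clip(cov, -0.999999, 0.999999))
    np.fill_diagonal(z, 0.0)
    for (i, j), dz in zip(effect.edges, off):
        if not (0 <= i < C and 0 <= j < C):
            raise ValueError("effect edge references component out of range")
        z[i, j] += dz
        z[j, i] += dz
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return _nearest_spd_correlation(r)


def _draw_state_sequence(
    T: int, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    k = P.shape[0]
    # start from the stationary distribution of the chain
    w, v = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, idx])
    pi = np.abs(pi) / np.abs(pi).sum()
    seq = np.empty(T, dtype=int)
    seq[0] = rng.choice(k, p=pi)
    for t in range(1, T):
        seq[t] = rng.choice(k, p=P[seq[t - 1]])
    return seq


def _random_motion(T: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random-walk realignment parameters (3 translations mm, 3 rotations rad)."""
    steps = rng.normal(scale=0.02, size=(T, 6))
    motion = np.cumsum(steps, axis=0)
    motion[:, 3:] *= 0.01  # rotations are small in rad
    return motion


def simulate_subject(
    spec: SubjectSimSpec,
    states: StateCovSet,
    effect: GroupEffectSpec | None = None,
) -> tuple["SubjectTimecourses", SimTruth]:
    """Simulate one subject's component timecourses with known truth."""
    from dfncstates.preprocess import SubjectTimecourses

    spec.validate(states.k)
    rng = np.random.default_rng(spec.seed)
    T, C, k = spec.T, states.C, states.k
    P = (
        np.asarray(spec.markov, dtype=float)
        if spec.markov is not None
        else np.full((k, k), 1.0 / k)
    )
    seq = _draw_state_sequence(T, P, rng) if k > 1 else np.zeros(T, dtype=int)

    chols = []
    for s in range(k):
        cov = apply_group_effect(states.covs[s], effect, s)
        chols.append(np.linalg.cholesky(cov))
    raw = rng.standard_normal(size=(T, C))
    data = np.empty((T, C))
    for s in range(k):
        mask = seq == s
        if mask.any():
            data[mask] = raw[mask] @ chols[s].T

    if spec.drift is not None:
        coeffs = np.atleast_1d(np.asarray(spec.drift, dtype=float))
        tnorm = np.linspace(0.0, 1.0, T)
        drift = np.polynomial.polynomial.polyval(tnorm, coeffs)
        data += drift[:, None]

    motion = _random_motion(T, rng)
    if spec.motion_coupling > 0:
        B = rng.normal(size=(6, C))
        data += spec.motion_coupling * (motion @ B)

    spike_times = np.array([], dtype=int)
    if spec.spike_rate > 0:
        n_spikes = rng.poisson(spec.spike_rate * T / 100.0)
        if n_spikes > 0:
            spike_times = np.sort(
                rng.choice(T, size=min(n_spikes, T), replace=False)
            )
            comps = rng.integers(0, C, size=spike_times.size)
            ampl = 5.0 * rng.standard_t(df=2, size=spike_times.size)
            data[spike_times, comps] += ampl

    tc = SubjectTimecourses(
        values=data,
        TR=spec.TR,
        component_ids=[f"IC{c + 1}" for c in range(C)],
    )
    truth = SimTruth(
        state_sequence=seq,
        states=states,
        effects=[effect] if effect is not None else [],
        motion=motion,
        spike_times=spike_times,
    )
    return tc, truth


def simulate_cohort(
    n_per_group: dict[str, int],
    shared_states: StateCovSet,
    effects: list[GroupEffectSpec] | None,
    base_spec: SubjectSimSpec,
) -> list[tuple[str, "SubjectTimecourses", SimTruth]]:
    """Simulate a multi-group cohort sharing one set of latent states.

    Group effects differ; the states are common. Per-subject seeds are
    derived deterministically from the base seed and the subject index, so
    the cohort is bitwise reproducible.
    """
    if len(set(n_per_group)) != len(n_per_group):
        raise ValueError("group labels must be distinct")
    if any(n <= 0 for n in n_per_group.values()):
        raise ValueError("every group must contain at least one subject")
    effect_by_group = {e.group: e for e in (effects or [])}
    cohort = []
    idx = 0
    for group, n in n_per_group.items():
        eff = effect_by_group.get(group)
        for _ in range(n):
            sub_seed = np.random.SeedSequence(
                entropy=base_spec.seed, spawn_key=(idx,)
            ).generate_state(1)[0] % (2**31)
            spec = SubjectSimSpec(
                T=base_spec.T,
                TR=base_spec.TR,
                markov=base_spec.markov,
                drift=base_spec.drift,
                spike_rate=base_spec.spike_rate,
                motion_coupling=base_spec.motion_coupling,
                seed=int(sub_seed),
            )
            tc, truth = simulate_subject(spec, shared_states, eff)
            cohort.append((group, tc, truth))
            idx += 1
    return cohort


def simulate_state_cohort(
    n_subjects: int = 20,
    k: int = 5,
    C: int = 10,
    T: int = 400,
    separation: float = 0.9,
    stay_prob: float = 0.99,
    seed: int = 0,
    TR: float = 1.5,
) -> tuple[list["SubjectTimecourses"], list[SimTruth], StateCovSet]:
    """Reference cohort for state-recovery validation.

    Defaults define the well-separated regime: strongly structured states
    with pattern correlation below 0.1, and dwell times (mean 1/(1-stay) =
    100 TRs) well above the 22-TR window width so most windows are pure.
    Returns (timecourses, truths, states).
    """
    states = make_state_cov_set(k, C, separation=separation, seed=seed)
    P = np.full((k, k), (1.0 - stay_prob) / max(k - 1, 1))
    np.fill_diagonal(P, stay_prob if k > 1 else 1.0)
    tcs, truths = [], []
    for i in range(n_subjects):
        sub_seed = np.random.SeedSequence(
            entropy=seed, spawn_key=(i,)
        ).generate_state(1)[0] % (2**31)
        tc, tr = simulate_subject(
            SubjectSimSpec(T=T, TR=TR, markov=P, seed=int(sub_seed)), states
        )
        tcs.append(tc)
        truths.append(tr)
    return tcs, truths, states


def mix_to_voxels(
    tc: "SubjectTimecourses",
    V: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    mixing: np.ndarray | None = None,
    support_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mix component timecourses into a voxel-by-time matrix.

    Spatial maps are sparse and non-negative: each component loads on a
    random voxel support. Returns ``(voxel_by_time, mixing)`` where
    ``mixing`` is the (V, C) spatial-map matrix.
    """
    C = tc.values.shape[1]
    if V < C:
        raise ValueError("V must be >= C")
    rng = np.random.default_rng(seed)
    if mixing is None:
        n_sup = max(3, int(round(support_fraction * V)))
        A = np.zeros((V, C))
        for c in range(C):
            sup = rng.choice(V, size=min(n_sup, V), replace=False)
            A[sup, c] = np.abs(rng.normal(loc=1.0, size=sup.size))
    else:
        A = np.asarray(mixing, dtype=float)
        if A.shape != (V, C):
            raise ValueError("mixing shape must be (V, C)")
    X = A @ tc.values.T
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    return X, A


def write_cohort(
    cohort: list[tuple[str, "SubjectTimecourses", SimTruth]],
    outdir: str | Path,
) -> None:
    """Write a cohort as delimited text plus a JSON truth/manifest file."""
    from dfncstates.io import write_timecourses, write_motion

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (group, tc, truth) in enumerate(cohort):
        stem = f"sub-{i:03d}"
        write_timecourses(outdir / f"{stem}_tc.tsv", tc)
        if truth.motion is not None:
            write_motion(outdir / f"{stem}_motion.tsv", truth.motion)
        manifest.append(
            {
                "subject": stem,
                "group": group,
                "T": int(tc.values.shape[0]),
                "C": int(tc.values.shape[1]),
                "TR": tc.TR,
                "state_sequence": truth.state_sequence.tolist(),
            }
        )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh)
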