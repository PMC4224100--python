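import numpy as np
import pytest

from dfncstates import (
    SubjectSimSpec,
    SubjectTimecourses,
    WindowSpec,
    compute_dfnc,
    glasso,
    make_state_cov_set,
    make_taper,
    select_lambda,
    simulate_subject,
    window_starts,
    windowed_cov,
)


class TestMakeTaper:
    def test_alpha_zero_is_rectangular(self):
        w = make_taper(WindowSpec(width=22, taper_param=0.0))
        np.testing.assert_allclose(w, 1.0)

    def test_alpha_one_is_hann(self):
        width = 22
        w = make_taper(WindowSpec(width=width, taper_param=1.0))
        n = np.arange(width)
        hann = 0.5 * (1 - np.cos(2 * np.pi * n / (width - 1)))
        np.testing.assert_allclose(w, hann, atol=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_symmetry_and_peak(self, alpha):
        w = make_taper(WindowSpec(width=23, taper_param=alpha))
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        assert w.max() == pytest.approx(1.0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(width=22, taper_param=1.5)


class TestWindowStarts:
    def test_single_window_boundary(self):
        assert list(window_starts(22, WindowSpec(width=22))) == [0]

    def test_default_run_yields_185_windows(self):
        # floor((206 - 22) / 1) + 1
        assert window_starts(206, WindowSpec()).size == 185

    def test_step_enumeration(self):
        assert list(window_starts(30, WindowSpec(width=10, step=5))) == [
            0, 5, 10, 15, 20,
        ]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            window_starts(10, WindowSpec(width=22))


class TestWindowedCov:
    def test_rectangular_taper_equals_sample_cov(self, rng):
        X = rng.normal(size=(50, 4))
        spec = WindowSpec(width=20, taper_param=0.0)
        S = windowed_cov(X, 10, spec)
        seg = X[10:30]
        np.testing.assert_allclose(S, np.cov(seg, rowvar=False, ddof=0), atol=1e-12)

    def test_duplicated_column_variance(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, x])
        spec = WindowSpec(width=30, taper_param=0.5)
        S = windowed_cov(X, 0, spec)
        assert S[0, 1] == pytest.approx(S[0, 0])

    def test_matches_summation_oracle(self, rng):
        X = rng.normal(size=(40, 3))
        spec = WindowSpec(width=22, taper_param=0.5)
        w = make_taper(spec)
        S = windowed_cov(X, 5, spec)
        seg = X[5:27]
        mu = (w[:, None] * seg).sum(0) / w.sum()
        expect = np.zeros((3, 3))
        for t in range(22):
            d = seg[t] - mu
            expect += w[t] * np.outer(d, d)
        expect /= w.sum()
        np.testing.assert_allclose(S, expect, atol=1e-10)


class TestGlasso:
    def test_unpenalized_limit_is_matrix_inverse(self, rng):
        M = rng.normal(size=(5, 5))
        S = M @ M.T + 5 * np.eye(5)
        fit = glasso(S, 0.0)
        np.testing.assert_allclose(fit.precision, np.linalg.inv(S), atol=1e-4)

    def test_full_shrinkage_limit_is_diagonal(self, rng):
        M = rng.normal(size=(4, 4))
        S = M @ M.T + np.eye(4)
        fit = glasso(S / np.outer(np.sqrt(np.diag(S)), np.sqrt(np.diag(S))), 5.0)
        off = fit.precision.copy()
        np.fill_diagonal(off, 0.0)
        assert np.abs(off).max() < 1e-10

    def test_objective_beats_random_perturbations(self, rng):
        M = rng.normal(size=(5, 5))
        S = M @ M.T + 3 * np.eye(5)
        S /= np.outer(np.sqrt(np.diag(S)), np.sqrt(np.diag(S)))
        lam = 0.1
        fit = glasso(S, lam)

        def objective(theta):
            sign, logdet = np.linalg.slogdet(theta)
            if sign <= 0:
                return -np.inf
            off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
            return logdet - np.trace(S @ theta) - lam * off

        best = objective(fit.precision)
        for _ in range(500):
            pert = rng.normal(scale=0.02, size=(5, 5))
            cand = fit.precision + (pert + pert.T) / 2
            assert objective(cand) <= best + 1e-6

    def test_support_nonincreasing_in_lambda(self, rng):
        M = rng.normal(size=(6, 6))
        S = M @ M.T + 2 * np.eye(6)
        S /= np.outer(np.sqrt(np.diag(S)), np.sqrt(np.diag(S)))
        grid = np.logspace(-2, 0, 10)
        prev = None
        for lam in grid:
            theta = glasso(S, lam).precision
            support = np.abs(theta) > 1e-8
            np.fill_diagonal(support, False)
            n_edges = support.sum()
            if prev is not None:
                assert n_edges <= prev + 2  # allow borderline-zero flips
            prev = n_edges

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            glasso(np.eye(3), -0.1)


def _sparse_precision_data(rng, C=10, T=400, density=0.4):
    """Time series whose true precision has a known sparse support."""
    theta = np.eye(C) * 2.0
    iu = np.triu_indices(C, k=1)
    mask = rng.random(iu[0].size) < density
    vals = rng.uniform(0.25, 0.4, size=iu[0].size) * np.where(rng.random(iu[0].size) < 0.5, -1, 1)
    theta[iu[0][mask], iu[1][mask]] = vals[mask]
    theta[iu[1][mask], iu[0][mask]] = vals[mask]
    w = np.linalg.eigvalsh(theta).min()
    if w < 0.3:
        theta += (0.3 - w) * np.eye(C)
    cov = np.linalg.inv(theta)
    X = rng.multivariate_normal(np.zeros(C), cov, size=T)
    support = np.zeros((C, C), dtype=bool)
    support[iu[0][mask], iu[1][mask]] = True
    return X, support


class TestSelectLambda:
    def test_single_lambda_returned(self, rng):
        X = rng.normal(size=(100, 4))
        spec = WindowSpec(width=22)
        covs = [windowed_cov(X, s, spec) for s in window_starts(100, spec)]
        assert select_lambda(covs, np.array([0.3]), 3) == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", [17, 101, 105])
    def test_support_recovery_f1(self, seed):
        """The parsimony (one-SE) rule recovers the planted precision
        support; the plain likelihood maximizer is consistent for the
        matrix values but over-selects edges by construction."""
        rng = np.random.default_rng(seed)
        X, support = _sparse_precision_data(rng)
        spec = WindowSpec(width=22)
        covs = [windowed_cov(X, int(s), spec) for s in window_starts(400, spec)]
        lam = select_lambda(covs, np.logspace(-2, 0, 10), 5, rule="1se")
        fit = glasso(np.cov(X, rowvar=False, ddof=0), lam)
        est = np.abs(np.triu(fit.precision, k=1)) > 1e-6
        tp = (est & support).sum()
        prec = tp / max(est.sum(), 1)
        rec = tp / max(support.sum(), 1)
        f1 = 2 * prec * rec / max(prec + rec, 1e-12)
        assert f1 >= 0.8

    def test_dense_truth_prefers_small_lambda(self):
        rng = np.random.default_rng(23)
        C = 6
        M = rng.normal(size=(C, C))
        cov = M @ M.T + C * np.eye(C)
        X = rng.multivariate_normal(np.zeros(C), cov, size=2000)
        spec = WindowSpec(width=50)
        covs = [windowed_cov(X, int(s), spec) for s in window_starts(2000, spec)[::10]]
        grid = np.logspace(-2, 0, 5)
        lam = select_lambda(covs, grid, 4)
        assert lam <= grid[1]


class TestComputeDfnc:
    def test_rectangular_lam0_equals_windowed_pearson(self, rng):
        X = rng.normal(size=(80, 4))
        tc = SubjectTimecourses(X, TR=1.5)
        spec = WindowSpec(width=22, taper_param=0.0)
        d = compute_dfnc(tc, spec, lam=0.0)
        for s in d.window_starts[::7]:
            r = np.corrcoef(X[s : s + 22], rowvar=False)
            z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
            np.fill_diagonal(z, 0.0)
            np.testing.assert_allclose(d.values[:, :, s], z, atol=1e-6)

    def test_slices_symmetric_zero_diagonal_finite(self, three_state_dfnc):
        _, _, dfnc, _ = three_state_dfnc
        assert np.isfinite(dfnc.values).all()
        for wi in range(0, dfnc.W, 50):
            sl = dfnc.values[:, :, wi]
            np.testing.assert_allclose(sl, sl.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(sl), 0.0, atol=1e-12)

    def test_stationary_limit_slices_nearly_equal(self, rng):
        # one shared signal driving every component + tiny independent noise:
        # windowed correlations sit near 1 in every window
        shared = np.cumsum(rng.normal(size=80))
        shared /= shared.std()
        X = shared[:, None] + rng.normal(scale=0.02, size=(80, 5))
        d = compute_dfnc(
            SubjectTimecourses(X, TR=1.5), WindowSpec(width=22), lam=0.0
        )
        r = np.tanh(d.edge_vectors())  # back to correlation scale
        spread = np.abs(r[:, None, :] - r[None, :, :]).max()
        assert spread < 0.05

    def test_state_switching_raises_edge_variance(self):
        k1 = make_state_cov_set(1, 6, seed=3)
        k3 = make_state_cov_set(3, 6, separation=0.9, seed=3)
        P = np.full((3, 3), 0.01)
        np.fill_diagonal(P, 0.98)
        tc1, _ = simulate_subject(SubjectSimSpec(T=400, seed=5), k1)
        tc3, _ = simulate_subject(SubjectSimSpec(T=400, markov=P, seed=5), k3)
        v1 = compute_dfnc(tc1, WindowSpec(), 0.0).edge_vectors().var(axis=0).mean()
        v3 = compute_dfnc(tc3, WindowSpec(), 0.0).edge_vectors().var(axis=0).mean()
        assert v3 > v1

    def test_changepoint_localized_within_one_width(self):
        rng = np.random.default_rng(31)
        states = make_state_cov_set(2, 5, separation=0.9, seed=9)
        chols = [np.linalg.cholesky(c) for c in states.covs]
        T, switch, width = 200, 100, 22
        raw = rng.standard_normal((T, 5))
        X = np.vstack(
            [raw[:switch] @ chols[0].T, raw[switch:] @ chols[1].T]
        )
        d = compute_dfnc(SubjectTimecourses(X, TR=1.5), WindowSpec(), 0.0)
        # edge with the largest planted contrast between the two states
        iu = np.triu_indices(5, k=1)
        diffs = np.abs(states.covs[0] - states.covs[1])[iu]
        e = int(np.argmax(diffs))
        trace = d.edge_vectors()[:, e]
        za = np.arctanh(states.covs[0][iu[0][e], iu[1][e]])
        zb = np.arctanh(states.covs[1][iu[0][e], iu[1][e]])
        # least-absolute-deviation changepoint fit of the edge trace to a
        # step from the state-0 level to the state-1 level
        costs = [
            np.abs(trace[:w] - za).sum() + np.abs(trace[w:] - zb).sum()
            for w in range(1, trace.size)
        ]
        est_switch = d.window_starts[1 + int(np.argmin(costs))] + width / 2
        assert abs(est_switch - switch) <= width
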