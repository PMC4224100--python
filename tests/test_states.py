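import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dfncstates import (
    SubjectSimSpec,
    WindowSpec,
    choose_k_elbow,
    cluster_states,
    compute_dfnc,
    kmeans_fit,
    make_state_cov_set,
    select_exemplars,
    simulate_subject,
    simulate_state_cohort,
    subject_summary,
)
from dfncstates.states import cluster_validity_ratio

from conftest import modal_window_labels


class _FakeDfnc:
    """Minimal stand-in carrying a precomputed window-by-edge matrix."""

    def __init__(self, vecs):
        self._vecs = np.asarray(vecs, dtype=float)
        self.W = self._vecs.shape[0]

    def edge_vectors(self):
        return self._vecs


def _dfnc_with_variability(var_series, rng):
    vecs = rng.normal(size=(len(var_series), 6))
    vecs = vecs - vecs.mean(axis=1, keepdims=True)
    sd = vecs.std(axis=1, keepdims=True)
    vecs = vecs / sd * np.asarray(var_series, dtype=float)[:, None]
    return _FakeDfnc(vecs)


class TestSelectExemplars:
    def test_local_maxima_enumeration(self, rng):
        d = _dfnc_with_variability([1, 3, 1, 5, 1], rng)
        assert list(select_exemplars(d)) == [1, 3]

    def test_increasing_series_keeps_last(self, rng):
        d = _dfnc_with_variability([1, 2, 3, 4, 5], rng)
        assert list(select_exemplars(d)) == [4]

    def test_constant_series_falls_back(self, rng):
        d = _dfnc_with_variability([2, 2, 2, 2, 2, 2, 2, 2, 2, 2], rng)
        with pytest.warns(UserWarning):
            picks = select_exemplars(d)
        assert picks.size >= 1

    def test_state_switching_subject_yields_enough_exemplars(self, three_state_dfnc):
        _, _, dfnc, _ = three_state_dfnc
        picks = select_exemplars(dfnc)
        assert picks.size >= 3


class TestKmeans:
    def test_separable_clouds_recovered(self, rng):
        a = rng.normal(size=(40, 5)) + 20
        b = rng.normal(size=(40, 5)) - 20
        pts = np.vstack([a, b])
        _, labels, _ = kmeans_fit(pts, 2, seed=1)
        assert len(np.unique(labels[:40])) == 1
        assert len(np.unique(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_k_equals_n_zero_inertia(self, rng):
        pts = rng.normal(size=(6, 3))
        _, _, inertia = kmeans_fit(pts, 6, seed=0)
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_l1_centroids_are_member_medians(self, rng):
        pts = rng.normal(size=(200, 4))
        pts[:100] += 6
        centroids, labels, _ = kmeans_fit(pts, 3, metric="l1", seed=2)
        for c in range(3):
            members = pts[labels == c]
            np.testing.assert_allclose(
                centroids[c], np.median(members, axis=0), atol=1e-12
            )

    def test_every_point_assigned_to_nearest_centroid(self, rng):
        pts = rng.normal(size=(150, 4))
        for metric in ("l1", "correlation", "cosine"):
            centroids, labels, _ = kmeans_fit(pts, 4, metric=metric, seed=3)
            from dfncstates.states import _distances

            D = _distances(pts, centroids, metric)
            np.testing.assert_array_equal(labels, D.argmin(axis=1))

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_fit(rng.normal(size=(3, 2)), 5)


class TestChooseKElbow:
    def test_five_separated_gaussians(self, rng):
        centers = rng.normal(size=(5, 20)) * 12
        pts = np.vstack(
            [c + rng.normal(size=(60, 20)) for c in centers]
        )
        k, _ = choose_k_elbow(pts, range(2, 11), seed=4)
        assert k == 5

    def test_single_tight_cluster_warns_smallest_k(self, rng):
        pts = rng.normal(scale=0.01, size=(100, 5)) + 7
        # structureless cloud: the ratio curve has no bend to find
        with pytest.warns(UserWarning):
            k, ratios = choose_k_elbow(pts, range(2, 8), seed=5)
        assert k == 2

    def test_too_narrow_range_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_k_elbow(rng.normal(size=(30, 3)), [2, 3])


@pytest.fixture(scope="module")
def clustered_cohort():
    tcs, truths, states = simulate_state_cohort(n_subjects=8, T=300, seed=5)
    spec = WindowSpec()
    dfncs = {
        f"sub{i}": compute_dfnc(tc, spec, lam=0.0) for i, tc in enumerate(tcs)
    }
    model = cluster_states(dfncs, 5, seed=9)
    return dfncs, truths, model


class TestClusterStates:
    def test_planted_partition_recovered(self, clustered_cohort):
        dfncs, truths, model = clustered_cohort
        true_labels = np.concatenate(
            [
                modal_window_labels(
                    truths[i].state_sequence, dfncs[f"sub{i}"].window_starts, 22
                )
                for i in range(len(truths))
            ]
        )
        assigned = np.concatenate(
            [model.assignments[f"sub{i}"] for i in range(len(truths))]
        )
        assert adjusted_rand_score(true_labels, assigned) >= 0.8

    def test_occurrence_percentages_sum_to_100(self, clustered_cohort):
        _, _, model = clustered_cohort
        assert model.percentages.sum() == pytest.approx(100.0, abs=0.01)
        assert model.counts.sum() == sum(
            len(a) for a in model.assignments.values()
        )

    def test_identical_subjects_have_identical_group_centroids(self):
        tcs, _, _ = simulate_state_cohort(n_subjects=1, k=3, C=6, T=300, seed=2)
        d = compute_dfnc(tcs[0], WindowSpec(), lam=0.0)
        dfncs = {"a": d, "b": d}
        model = cluster_states(
            dfncs, 3, seed=1, groups={"a": "G1", "b": "G2"}
        )
        np.testing.assert_allclose(
            model.group_centroids["G1"], model.group_centroids["G2"]
        )

    def test_two_stage_no_worse_than_random_init(self, clustered_cohort):
        dfncs, _, model = clustered_cohort
        pts = np.concatenate([d.edge_vectors() for d in dfncs.values()])
        _, _, best_random = kmeans_fit(pts, 5, n_replicates=5, seed=31)
        from dfncstates.states import _distances

        D = _distances(pts, model.centroids, "l1")
        two_stage = D.min(axis=1).sum()
        assert two_stage <= best_random * 1.001


class TestSubjectSummary:
    def test_hand_enumerated_sequence(self):
        s = subject_summary(np.array([0, 0, 1, 1, 0]), k=2)
        assert s.n_transitions == 2
        assert list(s.entries) == [1, 1]
        assert s.dwell_fractions[0] == pytest.approx(0.6)

    def test_constant_sequence(self):
        s = subject_summary(np.zeros(10, dtype=int), k=3)
        assert s.n_transitions == 0
        assert s.dwell_fractions[0] == 1.0
        assert s.entries.sum() == 0

    def test_fuzz_against_brute_force(self, rng):
        for _ in range(300):
            k = int(rng.integers(2, 6))
            labels = rng.integers(0, k, size=int(rng.integers(2, 40)))
            s = subject_summary(labels, k)
            trans = sum(
                1 for i in range(len(labels) - 1) if labels[i] != labels[i + 1]
            )
            assert s.n_transitions == trans
            for state in range(k):
                entries = sum(
                    1
                    for i in range(len(labels) - 1)
                    if labels[i + 1] == state and labels[i] != state
                )
                assert s.entries[state] == entries
            assert s.dwell_fractions.sum() == pytest.approx(1.0)

    def test_centroids_are_member_means(self, rng):
        vecs = rng.normal(size=(20, 4))
        labels = rng.integers(0, 2, size=20)
        s = subject_summary(labels, 2, vectors=vecs)
        for state in np.unique(labels):
            np.testing.assert_allclose(
                s.centroids[state], vecs[labels == state].mean(axis=0)
            )


class TestRecoveryDegradesWithSeparation:
    def test_ari_monotone_in_separation(self):
        """Recovery quality degrades on average as planted separation drops."""
        mean_aris = []
        for sep in (0.9, 0.1, 0.02):
            aris = []
            for seed in range(3):
                tcs, truths, _ = simulate_state_cohort(
                    n_subjects=6, T=300, separation=sep, seed=40 + seed
                )
                dfncs = {
                    f"s{i}": compute_dfnc(tc, WindowSpec(), 0.0)
                    for i, tc in enumerate(tcs)
                }
                model = cluster_states(dfncs, 5, seed=seed)
                tl = np.concatenate(
                    [
                        modal_window_labels(
                            truths[i].state_sequence,
                            dfncs[f"s{i}"].window_starts,
                            22,
                        )
                        for i in range(6)
                    ]
                )
                aa = np.concatenate(
                    [model.assignments[f"s{i}"] for i in range(6)]
                )
                aris.append(adjusted_rand_score(tl, aa))
            mean_aris.append(np.mean(aris))
        assert mean_aris[0] > mean_aris[2]
        assert mean_aris[0] >= mean_aris[1] - 0.1
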