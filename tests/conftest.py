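import numpy as np
import pytest

from dfncstates import (
    SubjectSimSpec,
    SubjectTimecourses,
    WindowSpec,
    compute_dfnc,
    make_state_cov_set,
    simulate_subject,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_state_tc():
    """Long single-state subject: empirical correlations near the planted ones."""
    states = make_state_cov_set(1, 6, seed=3)
    spec = SubjectSimSpec(T=5000, seed=7)
    tc, truth = simulate_subject(spec, states)
    return tc, states


@pytest.fixture(scope="session")
def three_state_dfnc():
    """One subject switching among 3 states, with its windowed connectivity."""
    states = make_state_cov_set(3, 8, separation=0.9, seed=11)
    P = np.full((3, 3), 0.01)
    np.fill_diagonal(P, 0.98)
    tc, truth = simulate_subject(
        SubjectSimSpec(T=400, markov=P, seed=21), states
    )
    dfnc = compute_dfnc(tc, WindowSpec(), lam=0.0)
    return tc, truth, dfnc, states


def modal_window_labels(state_sequence, starts, width):
    """Ground-truth label per window: the modal planted state inside it."""
    return np.array(
        [
            np.bincount(state_sequence[s : s + width]).argmax()
            for s in starts
        ]
    )
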