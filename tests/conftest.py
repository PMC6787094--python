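import numpy as np
import pytest

from consdyn import CohortSpec, FCMatrix, RoiTimeseries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """60-timepoint, 6-region random timeseries, TR = 2 s."""
    return RoiTimeseries(rng.standard_normal((60, 6)), tr_seconds=2.0)


@pytest.fixture
def random_fc(rng):
    """Random symmetric signed FC-like matrix, 12 nodes, unit diagonal."""
    a = rng.uniform(-1, 1, size=(12, 12))
    w = (a + a.T) / 2
    np.fill_diagonal(w, 1.0)
    return FCMatrix(weights=w)


@pytest.fixture
def two_clique_matrix():
    """Two disconnected 3-node positive cliques (within-weight 1)."""
    w = np.zeros((6, 6))
    w[:3, :3] = 1.0
    w[3:, 3:] = 1.0
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture
def tiny_cohort_spec():
    """Scaled-down cohort for fast end-to-end runs."""
    return CohortSpec(
        n_subjects_a=4,
        n_subjects_b=4,
        n_regions=20,
        n_timepoints={"awake": 80, "deep": 80, "patient": 90},
        seed=7,
    )


def exhaustive_best_partition(w, gamma=1.0):
    """Brute-force maximum signed modularity over all set partitions (N <= 8)."""
    from consdyn.graph_metrics import modularity_signed

    n = w.shape[0]
    best_q, best_assign = -np.inf, None
    for assign in _set_partitions(n):
        q = modularity_signed(w, np.asarray(assign), gamma)
        if q > best_q:
            best_q, best_assign = q, assign
    return best_q, np.asarray(best_assign)


def _set_partitions(n):
    """All assignments of n items to modules in restricted-growth form (1-based)."""

    def rec(i, max_label, current):
        if i == n:
            yield list(current)
            return
        for lab in range(1, max_label + 2):
            current.append(lab)
            yield from rec(i + 1, max(max_label, lab), current)
            current.pop()

    yield from rec(0, 0, [])
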