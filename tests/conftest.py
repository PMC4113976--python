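import numpy as np
import pytest

from swmnet.atlas import default_atlas
from swmnet.shrinkage import partial_correlations, shrink_covariance
from swmnet.synthetic import build_precision, simulate_cohort


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def small_cohort_net():
    """One n=15 cohort from a 100-edge model with its estimated network."""
    model = build_precision(n_edges=100, seed=42)
    data = simulate_cohort(model, 15, seed=43)
    net = partial_correlations(shrink_covariance(data.values), atlas=data.atlas)
    return model, data, net


def regression_partial_corr(sigma: np.ndarray, i: int, j: int) -> float:
    """Independent oracle: partial correlation of (i, j) given the rest,
    via the population regression-residual covariance (Schur complement)."""
    k = sigma.shape[0]
    rest = [t for t in range(k) if t not in (i, j)]
    s_aa = sigma[np.ix_([i, j], [i, j])]
    if rest:
        s_ab = sigma[np.ix_([i, j], rest)]
        s_bb = sigma[np.ix_(rest, rest)]
        cond = s_aa - s_ab @ np.linalg.solve(s_bb, s_ab.T)
    else:
        cond = s_aa
    return cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])


def floyd_warshall_distances(adj: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs shortest paths on a binary adjacency matrix."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for m in range(n):
        for a in range(n):
            for b in range(n):
                if d[a, m] + d[m, b] < d[a, b]:
                    d[a, b] = d[a, m] + d[m, b]
    return d
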