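import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import dynoc


def matched_column_correlations(C: np.ndarray, C_true: np.ndarray) -> np.ndarray:
    """Per-column Pearson r after optimal (Hungarian) column matching."""
    k = C_true.shape[1]
    corr = np.corrcoef(C.T, C_true.T)[:k, k:]
    rows, cols = linear_sum_assignment(-corr)
    return corr[rows, cols]


def brute_force_jackknife(x, y):
    """Independent leave-one-out Pearson oracle, one np.corrcoef per point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty(x.size)
    for t in range(x.size):
        keep = np.ones(x.size, dtype=bool)
        keep[t] = False
        out[t] = -np.corrcoef(x[keep], y[keep])[0, 1]
    return out


@pytest.fixture
def small_truth():
    return dynoc.make_truth(12, 2, overlap_fraction=0.2, T=6, seed=1)


@pytest.fixture
def noise_free_tensor(small_truth):
    return dynoc.simulate_group_tensors(small_truth, n_subjects=1, noise_sd=0.0, seed=0)[0]
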