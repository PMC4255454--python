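import numpy as np
import pytest

import fastla as fl


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def null50():
    """Standardized 50-gene x 73-sample null matrix (independent genes)."""
    return fl.preprocess(fl.simulate_null(50, 73, seed=1), transform=False)


@pytest.fixture
def small_null():
    """A 12-gene x 73-sample null matrix, standardized."""
    return fl.preprocess(fl.simulate_null(12, 73, seed=7), transform=False)


def brute_force_rho_diff(matrix, i, j, c):
    """Per-pair two-bin correlation loop: the independent screening oracle."""
    bins = fl.tertile_bins(matrix.values[c], matrix.gene_ids[c])
    out = []
    for idx in (bins.high_idx, bins.low_idx):
        a = matrix.values[i][idx]
        b = matrix.values[j][idx]
        obs = ~(np.isnan(a) | np.isnan(b))
        out.append(np.corrcoef(a[obs], b[obs])[0, 1])
    return out[0] - out[1]


def brute_force_mla(x1, x2, x3, n_bins=3):
    """Explicit-loop direct MLA oracle: bin, standardize, sum products."""
    order = np.argsort(x3, kind="stable")
    n = x3.size
    sizes = [n // n_bins] * n_bins
    outer = []
    lo, hi = 0, n_bins - 1
    while lo <= hi:
        outer.append(lo)
        if hi != lo:
            outer.append(hi)
        lo, hi = lo + 1, hi - 1
    for k in range(n % n_bins):
        sizes[outer[k]] += 1
    total = 0.0
    start = 0
    for size in sizes:
        idx = order[start:start + size]
        start += size
        a, b, c = x1[idx], x2[idx], x3[idx]
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        total += np.sum(za * zb * c.mean())
    return total / n
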