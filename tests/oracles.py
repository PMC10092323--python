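"""Independent reference implementations used only to check the package.

Each oracle is written from the mathematical definition, not by calling the
code under test.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm


def gotoh_local_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Affine-gap Smith-Waterman via the three-matrix Gotoh recursion.

    BLAST gap convention: a gap of length k costs gap_open + gap_extend * k.
    """
    n, m = len(a), len(b)
    neg = -1e9
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)
    f = np.full((n + 1, m + 1), neg)
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - first, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - first, f[i - 1][j] - gap_extend)
            h[i][j] = max(
                0.0,
                h[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]],
                e[i][j],
                f[i][j],
            )
            best = max(best, h[i][j])
    return best


def kruskal_wallis_h(values, groups) -> float:
    """Tie-corrected Kruskal-Wallis H from the textbook formula."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = values[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (pos + (pos + (j - i) - 1)) / 2.0
        pos += j - i
        i = j
    h = 0.0
    for g in np.unique(groups):
        r = ranks[groups == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def srange_cdf_inf_df(q: float, k: int) -> float:
    """CDF of the studentized range (k groups, infinite df) by 1-d quadrature."""
    if q <= 0:
        return 0.0

    def integrand(z):
        return k * norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q)) ** (k - 1)

    val, _ = quad(integrand, -9, 9, limit=200, epsabs=1e-10)
    return val


def dscf_pair_pvalue_exhaustive(x, y, k: int) -> float:
    """Exact permutation p-value of the DSCF pair statistic over all splits.

    Enumerates every way to label the pooled sample, recomputes the
    standardized rank-sum statistic, and refers the observed |z| to the
    permutation distribution through the same studentized-range transform
    used asymptotically. Feasible only for tiny groups.
    """
    from itertools import combinations

    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = nx + ny

    def zstat(idx_x):
        ranks = rankdata(pooled)
        w = ranks[list(idx_x)].sum()
        mean_w = nx * (n + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie = np.sum(counts**3 - counts) / (n * (n - 1))
        var_w = nx * ny / 12.0 * (n + 1 - tie)
        return (w - mean_w) / np.sqrt(var_w) if var_w > 0 else 0.0

    observed = abs(zstat(range(nx)))
    count = 0
    total = 0
    for combo in combinations(range(n), nx):
        total += 1
        if abs(zstat(combo)) >= observed - 1e-12:
            count += 1
    return count / total


def truncated_mvn_mean_grid(cov: np.ndarray, signs: np.ndarray, lim: float = 8.0, m: int = 80):
    """Mean of a zero-mean MVN restricted to an orthant, by dense grid summation.

    signs[i] = +1 restricts coordinate i to (0, inf), -1 to (-inf, 0).
    Only practical for dimension 3.
    """
    d = cov.shape[0]
    assert d == 3
    axes = []
    for s in signs:
        if s > 0:
            axes.append(np.linspace(1e-9, lim, m))
        else:
            axes.append(np.linspace(-lim, -1e-9, m))
    g = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=1)
    prec = np.linalg.inv(cov)
    logw = -0.5 * np.einsum("ij,jk,ik->i", pts, prec, pts)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return pts.T @ w
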