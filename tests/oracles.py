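"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: explicit double loops instead of vectorized
centering, scipy.linalg.expm instead of the cached eigendecomposition,
and scipy.stats.hypergeom enumeration instead of rational arithmetic.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm
from scipy.stats import hypergeom


def naive_dcov_dcor(a: np.ndarray, b: np.ndarray):
    """Distance covariance/correlation by the textbook double loop."""
    n = a.shape[0]

    def center(m):
        out = np.zeros((n, n))
        grand = sum(m[j][k] for j in range(n) for k in range(n)) / n**2
        for j in range(n):
            for k in range(n):
                rj = sum(m[j][l] for l in range(n)) / n
                ck = sum(m[l][k] for l in range(n)) / n
                out[j, k] = m[j][k] - rj - ck + grand
        return out

    A, B = center(a), center(b)
    v_ab = sum(A[j, k] * B[j, k] for j in range(n) for k in range(n)) / n**2
    v_aa = sum(A[j, k] ** 2 for j in range(n) for k in range(n)) / n**2
    v_bb = sum(B[j, k] ** 2 for j in range(n) for k in range(n)) / n**2
    dcov = math.sqrt(max(v_ab, 0.0))
    if v_aa <= 0 or v_bb <= 0:
        return dcov, 0.0
    return dcov, math.sqrt(max(v_ab, 0.0) / math.sqrt(v_aa * v_bb))


def exhaustive_perm_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation p for the dcov statistic by full enumeration."""
    n = a.shape[0]
    t_obs, _ = naive_dcov_dcor(a, b)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        idx = np.array(perm)
        t, _ = naive_dcov_dcor(a, b[np.ix_(idx, idx)])
        total += 1
        if t >= t_obs - 1e-12:
            count += 1
    return count / total


def fisher_enumeration(a, b, c, d, alternative="two-sided") -> float:
    """Fisher p by explicit enumeration of all margin-consistent tables."""
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, r1, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = rv.pmf(a)
    ks = np.arange(lo, hi + 1)
    pmf = rv.pmf(ks)
    if alternative == "greater":
        return float(pmf[ks >= a].sum())
    if alternative == "less":
        return float(pmf[ks <= a].sum())
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def jtt_grid_distance(counts: np.ndarray, Q: np.ndarray, pi: np.ndarray,
                      grid=None) -> float:
    """Grid-search ML distance using scipy's expm (no eigendecomposition)."""
    if grid is None:
        grid = np.arange(0.001, 5.0005, 0.001)
    log_pi = np.log(pi)
    best_d, best_ll = grid[0], -np.inf
    for d in grid:
        P = expm(Q * d)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = log_pi[:, None] + np.log(np.clip(P, 1e-300, None))
        ll = float((counts * lp).sum())
        if ll > best_ll:
            best_ll, best_d = ll, d
    return float(best_d)
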