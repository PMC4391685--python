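"""Distance-covariance congruence testing between labeled distance matrices.

Given two dissimilarity matrices over the same strains — e.g. a
resistance-gene distance matrix and a 16S rRNA (or multi-locus) distance
matrix — the test measures dependence with the sample distance covariance
of Szekely, Rizzo & Bakirov (2007), computed directly on the two
matrices:

    A_hat[j,k] = a[j,k] - rowmean_j - colmean_k + grandmean
    dcov^2     = (1/n^2) * sum_jk A_hat[j,k] * B_hat[j,k]
    dcor (R)   = dcov / sqrt(dvar_A * dvar_B)

The null distribution is built by jointly permuting the rows and columns
of one matrix (the Mantel-style exchangeability convention), with the
add-one Monte-Carlo p-value p = (1 + #{T_perm >= T_obs}) / (1 + n_perm).
For n <= 8 the full n! enumeration is available, giving an exact p.

No multiplicity correction is applied anywhere: the pipeline reports raw
per-comparison p-values, and callers comparing many gene pairs should
treat p-values in (0.001, 0.05] as suggestive rather than confirmatory.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CongruenceError, SchemaError
from .io_formats import DistanceMatrix

#: fewest shared strains for which a permutation test is meaningful
MIN_N = 4

#: largest n for which exhaustive (n!) permutation is allowed
MAX_EXHAUSTIVE_N = 8

#: relative tolerance under which a permuted statistic counts as a tie
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class CongruenceResult:
    """Outcome of one congruence test (one row of a Table-2-style report)."""

    R: float
    p: float
    n: int
    n_perm: int
    observed_dcov: float
    perm_stats: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        assert -1e-12 <= self.R <= 1 + 1e-12
        assert 0 < self.p <= 1


def align_matrices(
    A: DistanceMatrix, B: DistanceMatrix, subset=None
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Restrict two matrices to their shared labels, in a common order.

    The order is A's label order filtered to the intersection (and to
    ``subset`` if given), so the operation is deterministic.
    """
    shared = [lab for lab in A.labels if lab in set(B.labels)]
    if subset is not None:
        subset = set(subset)
        shared = [lab for lab in shared if lab in subset]
    if len(shared) < MIN_N:
        raise CongruenceError(
            f"only {len(shared)} shared strains; need at least {MIN_N}"
        )
    return A.submatrix(shared), B.submatrix(shared)


def double_center(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Double-center a dissimilarity matrix: rows and columns sum to zero."""
    a = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _dcov2(Ahat: np.ndarray, Bhat: np.ndarray) -> float:
    return float((Ahat * Bhat).mean())


def dcov_dcor(A: DistanceMatrix, B: DistanceMatrix) -> tuple[float, float]:
    """Sample distance covariance and distance correlation of two matrices.

    Both matrices must carry identical labels in identical order.  If
    either matrix is degenerate (zero distance variance), R is 0.
    """
    if A.labels != B.labels:
        raise CongruenceError("matrices must share identical labels in identical order")
    Ahat, Bhat = double_center(A), double_center(B)
    v_ab = max(_dcov2(Ahat, Bhat), 0.0)
    v_aa = _dcov2(Ahat, Ahat)
    v_bb = _dcov2(Bhat, Bhat)
    dcov = math.sqrt(v_ab)
    if v_aa <= 0 or v_bb <= 0:
        return dcov, 0.0
    R = math.sqrt(v_ab / math.sqrt(v_aa * v_bb))
    return dcov, min(R, 1.0)


def dcov_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
    keep_perm_stats: bool = False,
) -> CongruenceResult:
    """Permutation test of dependence between two distance matrices.

    The statistic is the distance covariance; the null permutes the strain
    labels of ``B`` (rows and columns jointly).  ``exhaustive`` enumerates
    all n! permutations (n <= 8) and returns the exact p; otherwise
    ``n_perm`` uniform random permutations give an add-one Monte-Carlo p.
    Ties (|T_perm - T_obs| within relative 1e-12) count as >= observed.
    """
    if A.labels != B.labels:
        raise CongruenceError("matrices must share identical labels in identical order")
    n = A.n
    if n < MIN_N:
        raise CongruenceError(f"n = {n} < {MIN_N}")
    if not exhaustive and n_perm < 99:
        raise CongruenceError("n_perm must be >= 99 (or use exhaustive mode)")
    Ahat, Bhat = double_center(A), double_center(B)
    v_ab_obs = max(_dcov2(Ahat, Bhat), 0.0)
    t_obs = math.sqrt(v_ab_obs)
    _, R = dcov_dcor(A, B)

    # double-centering commutes with joint row/column permutation, so each
    # permuted statistic is computable from the pre-centered matrices
    def stat(perm) -> float:
        return math.sqrt(max(_dcov2(Ahat, Bhat[np.ix_(perm, perm)]), 0.0))

    thresh = t_obs - _TIE_RTOL * max(t_obs, 1.0)
    if exhaustive:
        if n > MAX_EXHAUSTIVE_N:
            raise CongruenceError(
                f"exhaustive enumeration limited to n <= {MAX_EXHAUSTIVE_N}, got {n}"
            )
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        stats = np.array([stat(p) for p in perms])
        n_used = len(perms)
        p_val = float(np.count_nonzero(stats >= thresh)) / n_used
    else:
        rng = np.random.default_rng(seed)
        stats = np.empty(n_perm)
        for r in range(n_perm):
            stats[r] = stat(rng.permutation(n))
        n_used = n_perm
        p_val = (1.0 + np.count_nonzero(stats >= thresh)) / (1.0 + n_perm)
    return CongruenceResult(
        R=R,
        p=p_val,
        n=n,
        n_perm=n_used,
        observed_dcov=t_obs,
        perm_stats=stats if keep_perm_stats else None,
    )


def mantel_r(A: DistanceMatrix, B: DistanceMatrix) -> float:
    """Pearson correlation of the off-diagonal entries (secondary output)."""
    if A.labels != B.labels:
        raise CongruenceError("matrices must share identical labels in identical order")
    iu = np.triu_indices(A.n, k=1)
    return float(np.corrcoef(A.values[iu], B.values[iu])[0, 1])


def environment_distance(
    meta: pd.DataFrame, variables, standardize: bool = True
) -> DistanceMatrix:
    """Euclidean distances between strains over selected site covariates.

    ``meta`` follows the site-metadata schema (strain, site, pH,
    organic_matter, ...).  With ``standardize`` each variable is z-scored
    (sample standard deviation) before the Euclidean distance, so
    covariates on different scales contribute comparably.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in meta.columns]
    if missing:
        raise SchemaError(f"site metadata missing variable columns {missing}")
    X = meta[variables].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    diff = X[:, None, :] - X[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(tuple(meta["strain"].astype(str)), vals)
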