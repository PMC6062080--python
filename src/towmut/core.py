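"""Largest-eigenvalue score test of multiple traits against an optimally
weighted variant combination, with permutation inference.

The test treats the weighted genotype burden ``x_i = sum_m w_m x_im`` as the
response of a linear model on the K (centered) traits and maximizes the score
statistic over the weight vector ``w``. With ``A = diag(X'X / n)``, the
maximized statistic is the largest eigenvalue

    T = lambda_max( A^{-1/2} X'Y (Y'Y)^{-1} Y'X A^{-1/2} )
      = lambda_max( (Y'Y)^{-1} Y' C Y ),        C = X A^{-1} X',

and the maximizing weights are ``w0 = A^{-1/2} W0`` with ``W0`` the leading
eigenvector of the symmetric form. Significance is assessed by jointly
permuting the rows of the trait matrix; ``C`` and ``(Y'Y)^{-1}`` are fixed
under permutation and are computed once.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

from .containers import RegionTestResult, WeightVector
from .exceptions import CollinearTraitsError, TowmutError

logger = logging.getLogger(__name__)

# A residualized genotype column whose mean square falls below this is
# treated as monomorphic (zero information) and dropped. Dosage variances of
# genuinely polymorphic variants are >= O(1/n), far above this floor.
_MONOMORPHIC_TOL = 1e-10

__all__ = [
    "centralize",
    "mean_impute",
    "diag_scale",
    "drop_monomorphic",
    "kernel_matrix",
    "towmut_statistic",
    "optimal_weights",
    "permutation_pvalue",
]


def centralize(matrix: np.ndarray) -> np.ndarray:
    """Subtract the column mean from every column.

    Raises
    ------
    TowmutError
        If the input is empty or has fewer than two rows.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.size == 0:
        raise TowmutError("cannot centralize an empty matrix")
    if arr.shape[0] < 2:
        raise TowmutError("centralize requires at least two rows")
    return arr - arr.mean(axis=0)


def mean_impute(matrix: np.ndarray) -> np.ndarray:
    """Replace missing (NaN) entries with their column mean.

    Columns that are entirely missing become all-zero (and will later be
    dropped as monomorphic). The number of imputed entries is logged.
    """
    arr = np.array(matrix, dtype=float)
    missing = np.isnan(arr)
    n_missing = int(missing.sum())
    if n_missing:
        col_mean = np.nanmean(np.where(missing.all(axis=0), 0.0, arr), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        arr[missing] = np.broadcast_to(col_mean, arr.shape)[missing]
        logger.warning("mean-imputed %d missing genotype entries", n_missing)
    return arr


def diag_scale(Xc: np.ndarray) -> np.ndarray:
    """Diagonal of ``X'X / n`` for a column-centered genotype matrix.

    Returned as a length-M vector of the diagonal entries
    ``A_mm = (1/n) sum_i x_im^2`` (the per-variant mean squares).
    """
    Xc = np.asarray(Xc, dtype=float)
    return np.einsum("ij,ij->j", Xc, Xc) / Xc.shape[0]


def drop_monomorphic(Xc: np.ndarray, variant_ids=None):
    """Drop centered genotype columns with (numerically) zero variance.

    A constant column carries no association information and would make the
    ``A`` matrix singular. Returns ``(Xc_kept, kept_mask)`` and logs a
    warning naming how many variants were removed.
    """
    Xc = np.asarray(Xc, dtype=float)
    A = diag_scale(Xc)
    kept = A > _MONOMORPHIC_TOL
    n_dropped = int((~kept).sum())
    if n_dropped:
        if variant_ids is not None:
            dropped = [variant_ids[m] for m in np.flatnonzero(~kept)]
            logger.warning(
                "dropped %d monomorphic variant(s): %s", n_dropped, dropped
            )
        else:
            logger.warning("dropped %d monomorphic variant(s)", n_dropped)
    if kept.sum() == 0:
        raise TowmutError("all variants are monomorphic; region is untestable")
    return Xc[:, kept], kept


def kernel_matrix(Xc: np.ndarray, A: np.ndarray) -> np.ndarray:
    """The n-by-n kernel ``C = X A^{-1} X'`` of the centered genotypes.

    ``C`` is symmetric positive semidefinite with rank at most M and trace
    ``n * M`` when no column is monomorphic.
    """
    Xc = np.asarray(Xc, dtype=float)
    A = np.asarray(A, dtype=float).ravel()
    if np.any(A <= 0):
        raise TowmutError("kernel_matrix requires strictly positive A entries")
    G = Xc / np.sqrt(A)
    return G @ G.T


def _trait_cholesky(Yc: np.ndarray) -> np.ndarray:
    """Cholesky factor of Y'Y, raising a named error when traits are collinear."""
    Yc = np.asarray(Yc, dtype=float)
    YtY = Yc.T @ Yc
    # detect rank deficiency via pivoted QR so the offending columns can be named
    _, R, piv = scipy.linalg.qr(Yc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Yc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    deficient = diag <= tol
    if deficient.any() or diag.size < Yc.shape[1]:
        bad = sorted(piv[np.flatnonzero(deficient)].tolist())
        raise CollinearTraitsError(bad)
    try:
        return np.linalg.cholesky(YtY)
    except np.linalg.LinAlgError:  # pragma: no cover - caught above in practice
        raise CollinearTraitsError(range(Yc.shape[1]))


def _scaled_genotypes(Xc: np.ndarray) -> np.ndarray:
    """``G = Xc A^{-1/2}`` so that ``C = G G'`` and ``Y'CY = (G'Y)'(G'Y)``."""
    A = diag_scale(Xc)
    return Xc / np.sqrt(A)


def _check_shapes(Xc, Yc):
    Xc = np.asarray(Xc, dtype=float)
    Yc = np.asarray(Yc, dtype=float)
    if Yc.ndim == 1:
        Yc = Yc[:, None]
    if Xc.ndim != 2 or Yc.ndim != 2:
        raise TowmutError("genotype and trait inputs must be 2-D")
    if Xc.shape[0] != Yc.shape[0]:
        raise TowmutError("genotype and trait matrices disagree on sample count")
    n, K = Yc.shape
    if n <= K:
        raise TowmutError("need more samples than traits (n > K)")
    return Xc, Yc


def towmut_statistic(Xc: np.ndarray, Yc: np.ndarray) -> float:
    """The maximized score statistic for centered genotypes and traits.

    Computed from the symmetric positive-semidefinite form: with
    ``G = Xc A^{-1/2}`` and ``Y'Y = L L'``, the statistic is the largest
    squared singular value of ``G'Y L^{-T}``.
    """
    Xc, Yc = _check_shapes(Xc, Yc)
    G = _scaled_genotypes(Xc)
    L = _trait_cholesky(Yc)
    B = G.T @ Yc  # M x K
    W = scipy.linalg.solve_triangular(L, B.T, lower=True).T  # B L^{-T}
    s = np.linalg.svd(W, compute_uv=False)
    return float(s[0] ** 2)


def optimal_weights(Xc: np.ndarray, Yc: np.ndarray):
    """The statistic together with the weight vector attaining it.

    The weights are ``w0 = A^{-1/2} W0`` where ``W0`` is the leading left
    singular vector of ``G'Y L^{-T}``; they are defined up to a nonzero
    scalar multiple.
    """
    Xc, Yc = _check_shapes(Xc, Yc)
    A = diag_scale(Xc)
    if np.any(A <= _MONOMORPHIC_TOL):
        raise TowmutError(
            "monomorphic variants present; drop them before computing weights"
        )
    G = Xc / np.sqrt(A)
    L = _trait_cholesky(Yc)
    W = scipy.linalg.solve_triangular(L, (G.T @ Yc).T, lower=True).T
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    w0 = U[:, 0] / np.sqrt(A)
    return float(s[0] ** 2), WeightVector(w0)


def _perm_batches(B: int, n: int):
    """Fixed batch partition of the B permutations, a function of (B, n) only.

    The permutation stream consumed from the seeded generator therefore
    depends only on ``(seed, B, n)`` regardless of memory constraints.
    """
    per_batch = max(1, min(B, 4_000_000 // max(n, 1)))
    start = 0
    while start < B:
        yield min(per_batch, B - start)
        start += per_batch


def _permutation_statistics(
    G: np.ndarray,
    Yc: np.ndarray,
    B: int,
    rng: np.random.Generator,
    per_trait: bool = False,
):
    """Statistics of B row-permutations of ``Yc`` against fixed genotypes.

    Parameters
    ----------
    G : (n, M) array
        Scaled centered genotypes ``Xc A^{-1/2}`` (so ``C = G G'``).
    per_trait : bool
        Additionally return the (B, K) matrix of single-trait statistics
        ``y_k' C y_k / y_k' y_k`` from the same permutation stream.

    Returns
    -------
    stats : (B,) array of largest-eigenvalue statistics
    trait_stats : (B, K) array or None
    """
    n, K = Yc.shape
    M = G.shape[1]
    L = _trait_cholesky(Yc)
    Linv = scipy.linalg.solve_triangular(L, np.eye(K), lower=True)
    trait_ss = np.einsum("ik,ik->k", Yc, Yc)
    base = np.arange(n)
    stats = np.empty(B)
    trait_stats = np.empty((B, K)) if per_trait else None
    pos = 0
    for b in _perm_batches(B, n):
        idx = rng.permuted(np.tile(base, (b, 1)), axis=1)
        Yp = np.take(Yc, idx, axis=0)  # (b, n, K)
        Ypt = np.ascontiguousarray(Yp.transpose(0, 2, 1)).reshape(b * K, n)
        Bm = (Ypt @ G).reshape(b, K, M)  # per-permutation Y'G blocks
        if per_trait:
            trait_stats[pos : pos + b] = (
                np.einsum("bkm,bkm->bk", Bm, Bm) / trait_ss
            )
        S = Bm @ Bm.transpose(0, 2, 1)  # Y' C Y, (b, K, K)
        Ms = Linv @ S @ Linv.T
        stats[pos : pos + b] = np.linalg.eigvalsh(Ms)[:, -1]
        pos += b
    return stats, trait_stats


def _count_pvalue(perm_stats: np.ndarray, observed: float, plus_one: bool) -> float:
    count = int(np.sum(perm_stats >= observed))
    B = perm_stats.size
    if plus_one:
        return (1 + count) / (1 + B)
    return count / B


def permutation_pvalue(
    X: np.ndarray,
    Y: np.ndarray,
    B: int,
    seed: int,
    *,
    centered: bool = False,
    plus_one: bool = False,
    method: str = "towmut",
) -> RegionTestResult:
    """Permutation test of the maximized score statistic.

    Rows of the trait matrix are shuffled jointly (each individual's K-vector
    stays together). The p-value counts permuted statistics that meet or
    exceed the observed one, divided by ``B``; it can be exactly 0 under this
    convention. Pass ``plus_one=True`` for the (1 + count) / (1 + B) variant,
    which is never 0.

    Parameters
    ----------
    X, Y : arrays
        Genotype dosages (n, M) and traits (n, K). Centered internally
        unless ``centered=True`` (e.g. inputs already residualized on
        covariates). Missing genotypes are mean-imputed; monomorphic
        variants are dropped with a logged warning.
    B : int
        Number of permutations (>= 1).
    seed : int
        Seeds the permutation stream, a pure function of ``(seed, B, n)``.
    """
    if B < 1:
        raise TowmutError("number of permutations B must be >= 1")
    if not centered:
        X = centralize(mean_impute(X))
        Y = centralize(Y)
    X, Y = _check_shapes(np.asarray(X, float), np.asarray(Y, float))
    Xk, _ = drop_monomorphic(X)
    statistic, weights = optimal_weights(Xk, Y)
    G = _scaled_genotypes(Xk)
    rng = np.random.default_rng(seed)
    perm_stats, _ = _permutation_statistics(G, Y, B, rng)
    p = _count_pvalue(perm_stats, statistic, plus_one)
    return RegionTestResult(
        statistic=statistic,
        p_value=p,
        n_permutations=B,
        optimal_weights=weights,
        method=method,
        seed=seed,
    )
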