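"""Covariate adjustment by residualizing traits and genotypes.

Both the trait matrix and the genotype matrix are regressed column-by-column
on the augmented covariate design ``D = [1 | Z]`` by ordinary least squares,
and the region test is applied to the residuals. Binary traits are
residualized by the same linear model as quantitative ones. Because the
residual-maker ``I - P`` (with ``P`` the orthogonal projector onto the
column space of ``D``) is idempotent, the adjusted score statistic computed
from residuals coincides with the score statistic of the joint linear model
that includes the covariates under the null.
"""

from __future__ import annotations

import numpy as np

from .containers import RegionTestResult
from .core import centralize, mean_impute, permutation_pvalue
from .exceptions import CollinearCovariatesError, TowmutError

__all__ = ["residualize", "towmut_with_covariates"]


def _design(Z: np.ndarray | None, n: int) -> np.ndarray:
    """Augmented design [1 | Z]; the intercept is always included."""
    ones = np.ones((n, 1))
    if Z is None:
        return ones
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[1] == 0:
        return ones
    if Z.shape[0] != n:
        raise TowmutError("covariate matrix disagrees on sample count")
    return np.hstack([ones, Z])


def residualize(M: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """OLS residuals of every column of ``M`` on the design ``[1 | Z]``.

    Computed through a thin QR decomposition of the design rather than the
    normal equations, for numerical stability. With no covariates this
    reduces to column centering. Residual columns sum to zero.

    Raises
    ------
    CollinearCovariatesError
        If ``[1 | Z]`` is rank deficient.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n = M.shape[0]
    D = _design(Z, n)
    if n <= D.shape[1]:
        raise TowmutError("need more samples than covariates plus intercept")
    Q, R = np.linalg.qr(D)
    rdiag = np.abs(np.diag(R))
    if rdiag.min() <= max(D.shape) * np.finfo(float).eps * rdiag.max():
        raise CollinearCovariatesError(
            "covariate design [1 | Z] is rank deficient (collinear covariates)"
        )
    return M - Q @ (Q.T @ M)


def towmut_with_covariates(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray | None,
    B: int,
    seed: int,
    *,
    plus_one: bool = False,
) -> RegionTestResult:
    """Covariate-adjusted region test.

    Equivalent, statistic and p-value alike, to running the unadjusted test
    on ``residualize(X, Z)`` and ``residualize(Y, Z)`` with the same seed.
    With ``Z=None`` this is exactly the unadjusted (centered) test.
    """
    X = mean_impute(X)
    if Z is None:
        Xr, Yr = centralize(X), centralize(Y)
    else:
        Xr = residualize(X, Z)
        Yr = residualize(Y, Z)
    return permutation_pvalue(
        Xr,
        Yr,
        B,
        seed,
        centered=True,
        plus_one=plus_one,
        method="towmut" if Z is None else "towmut+covariates",
    )
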