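"""Comparison tests: MANOVA via Wilks' lambda and the per-trait min-p test.

MANOVA fits the multivariate regression ``Y = X beta + eps`` and tests
``beta = 0`` with the likelihood-ratio statistic ``-n log(|E| / |E + H|)``,
where ``H = bhat' (X'X) bhat`` and ``E = Y'Y - H``. The min-p test runs the
single-trait optimally weighted test on every trait separately and combines
the K permutation p-values through their minimum, calibrated against the
same permutation stream.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.linalg
import scipy.stats

from .containers import BINARY, ManovaResult, SingleTowResult
from .core import (
    _permutation_statistics,
    _scaled_genotypes,
    centralize,
    drop_monomorphic,
    mean_impute,
    towmut_statistic,
)
from .exceptions import DegenerateFitError, TowmutError

logger = logging.getLogger(__name__)

__all__ = ["manova_wilks", "tow_single_trait", "single_tow"]


def manova_wilks(X, Y, trait_types=None, df: str = "mk") -> ManovaResult:
    """Wilks' lambda likelihood-ratio test of ``Y = X beta + eps``.

    Parameters
    ----------
    X, Y : arrays
        Genotypes (n, M) and traits (n, K); centered internally.
    trait_types : sequence, optional
        If any trait is flagged binary a warning is emitted: the normal
        likelihood behind Wilks' lambda is misspecified for case/control
        traits and the asymptotic reference can be anticonservative.
    df : {"mk", "k"}
        Degrees of freedom of the chi-square reference. ``"mk"`` (default)
        uses M*K, the number of constrained coefficients; ``"k"`` uses K.

    Raises
    ------
    TowmutError
        If ``X'X`` is singular (prune collinear variants first).
    DegenerateFitError
        If the residual cross-product matrix ``E`` is singular.
    """
    if trait_types is not None and BINARY in list(trait_types):
        warnings.warn(
            "MANOVA assumes multivariate-normal traits; binary traits can "
            "inflate its type I error",
            UserWarning,
            stacklevel=2,
        )
    Xc = centralize(mean_impute(X))
    Yc = centralize(Y)
    n, M = Xc.shape
    K = Yc.shape[1]
    XtX = Xc.T @ Xc
    if n <= M or np.linalg.matrix_rank(Xc) < M:
        raise TowmutError(
            "X'X is singular; prune collinear or monomorphic variants before "
            "running MANOVA"
        )
    beta = scipy.linalg.solve(XtX, Xc.T @ Yc, assume_a="pos")
    H = beta.T @ XtX @ beta
    E = Yc.T @ Yc - H
    sign_E, logdet_E = np.linalg.slogdet(E)
    sign_EH, logdet_EH = np.linalg.slogdet(E + H)
    if sign_E <= 0 or sign_EH <= 0:
        raise DegenerateFitError("residual matrix E is singular or indefinite")
    log_lambda = logdet_E - logdet_EH  # log(|E| / |E + H|) <= 0
    statistic = max(0.0, -n * log_lambda)
    if df == "mk":
        dof = M * K
    elif df == "k":
        dof = K
    else:
        raise TowmutError("df must be 'mk' or 'k'")
    p = float(scipy.stats.chi2.sf(statistic, dof))
    return ManovaResult(
        wilks_lambda=float(np.exp(log_lambda)),
        statistic=float(statistic),
        df=dof,
        p_value=p,
    )


def tow_single_trait(Xc: np.ndarray, y: np.ndarray) -> float:
    """Single-trait optimally weighted statistic (the K = 1 special case).

    Equals ``(y' C y) / (y' y)`` for the genotype kernel ``C``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise TowmutError("trait is constant; single-trait test undefined")
    return towmut_statistic(Xc, y[:, None])


def _min_p_overall(obs_traits: np.ndarray, trait_stats: np.ndarray) -> float:
    """Overall min-p permutation p-value from shared-stream trait statistics.

    Each permutation's per-trait statistic is converted to a p-value by its
    descending rank among the B permutations (ties counted as >=); the
    overall p-value is the fraction of permutations whose min-p is at most
    the observed min-p.
    """
    B = trait_stats.shape[0]
    per_trait_p = (trait_stats >= obs_traits).mean(axis=0)
    ranks = scipy.stats.rankdata(-trait_stats, method="max", axis=0)
    min_p_perm = (ranks / B).min(axis=1)
    return float(np.mean(min_p_perm <= per_trait_p.min()))


def single_tow(X, Y, B: int, seed: int) -> SingleTowResult:
    """Min-p combination of K single-trait permutation tests.

    All K traits share one permutation stream: in each permutation the rows
    of the full trait matrix are shuffled jointly, every trait's statistic is
    recomputed, and each permuted statistic is converted to a p-value by its
    rank among the B permutations. The observed statistic is the minimum of
    the K observed p-values; the reported p-value is the fraction of
    permutations whose own min-p is at most the observed one.
    """
    if B < 1:
        raise TowmutError("number of permutations B must be >= 1")
    Xc = centralize(mean_impute(X))
    Yc = centralize(Y)
    Xk, _ = drop_monomorphic(Xc)
    G = _scaled_genotypes(Xk)
    K = Yc.shape[1]
    for k in range(K):
        if np.ptp(Yc[:, k]) == 0:
            raise TowmutError(f"trait column {k} is constant")
    trait_ss = np.einsum("ik,ik->k", Yc, Yc)
    GtY = G.T @ Yc
    obs = np.einsum("mk,mk->k", GtY, GtY) / trait_ss
    rng = np.random.default_rng(seed)
    _, trait_stats = _permutation_statistics(G, Yc, B, rng, per_trait=True)
    per_trait_p = (trait_stats >= obs).mean(axis=0)
    observed_min_p = float(per_trait_p.min())
    p = _min_p_overall(obs, trait_stats)
    return SingleTowResult(
        per_trait_pvalues=per_trait_p,
        statistic=observed_min_p,
        p_value=p,
        n_permutations=B,
        seed=seed,
    )
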