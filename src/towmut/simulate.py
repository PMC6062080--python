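"""Synthetic data generation and Monte-Carlo harnesses.

The generator emulates the study design used to validate the test: a
100-variant "super gene" whose minor-allele-frequency spectrum is dominated
by rare variants, K = 10 correlated traits produced by a latent factor model
with two covariates, causal effects confined to rare variants (MAF < 0.01)
with heritability partitioned randomly across traits and variants, and
binary traits obtained by a liability threshold at one standard deviation
above the mean (prevalence 1 - Phi(1) ~ 16%).

Trait model
-----------
For one individual the K-vector of quantitative traits is

    y = (0.5 Z1 + 0.5 Z2) 1 + lambda + c * gamma f + sqrt(1 - c^2) eps,

where Z1 ~ N(0,1) and Z2 ~ Bernoulli(0.5) are covariates, ``lambda`` holds
the genotype effects (sum of beta-weighted risk dosages minus beta-weighted
protective dosages, nonzero only for the genotype-affected traits),
``f ~ MVN(0, (1-rho) I + rho J)`` are R latent factors with ``J`` the
all-ones matrix, ``gamma`` is the K-by-R 0/1 loading matrix, and the
``eps_k`` are independent standard normals. Trait pairs loading on the same
factor have correlation ``c^2``; pairs on different factors ``rho * c^2``.

Six model layouts are supported: (1) one factor, six affected traits;
(2) five factors, six affected; (3) two factors, six affected; (4) five
factors, one affected; (5) two factors, one affected; (6) K independent
factors with c = 1, six affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .compare import _min_p_overall
from .containers import (
    BINARY,
    QUANTITATIVE,
    CovariateMatrix,
    GenotypeMatrix,
    SimulationEstimate,
    TraitMatrix,
)
from .core import (
    _MONOMORPHIC_TOL,
    _permutation_statistics,
    _scaled_genotypes,
    _trait_cholesky,
    centralize,
    diag_scale,
)
from .covariates import residualize
from .exceptions import TowmutError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeSpectrumSpec",
    "CausalConfig",
    "HeritabilityAllocation",
    "FactorModelSpec",
    "sample_mafs",
    "generate_genotypes",
    "select_causal",
    "allocate_heritability",
    "effect_sizes",
    "generate_traits",
    "dichotomize",
    "binomial_ci",
    "estimate_type1_error",
    "estimate_power",
]

# Traits the genotypes act on, per model layout.
_N_AFFECTED = {1: 6, 2: 6, 3: 6, 4: 1, 5: 1, 6: 6}
_N_FACTORS = {1: 1, 2: 5, 3: 2, 4: 5, 5: 2}  # model 6: R = K


def _rng_from(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class GenotypeSpectrumSpec:
    """MAF spectrum of the synthetic 100-variant super gene.

    The spectrum is a three-component mixture: a ``fraction_rare`` mass of
    rare variants with MAF uniform on (``maf_floor``, ``rare_threshold``),
    a ``fraction_in_window`` mass with MAF uniform on the low-frequency
    window (0.01, 0.035), and the remainder common with MAF uniform on
    (0.035, 0.5). The floor 0.0007 ~ 1/(2 * 697) is the smallest allele
    frequency observable in a reference panel of 697 individuals.
    """

    M: int = 100
    rare_threshold: float = 0.01
    fraction_rare: float = 0.90
    fraction_in_window: float = 0.08
    window: tuple[float, float] = (0.01, 0.035)
    common_max: float = 0.5
    maf_floor: float = 0.0007
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.rare_threshold < 0.5:
            raise TowmutError("rare_threshold must lie in (0, 0.5)")
        if not 0 <= self.fraction_in_window <= 1:
            raise TowmutError("fraction_in_window must lie in [0, 1]")
        if self.fraction_rare + self.fraction_in_window > 1:
            raise TowmutError("mixture fractions exceed 1")
        if self.M < 1:
            raise TowmutError("M must be >= 1")


@dataclass
class CausalConfig:
    """Which variants carry effects: a random subset of the rare ones."""

    pct_causal_of_rare: float = 0.2
    pct_protective: float = 0.0
    rare_threshold: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.pct_protective <= 1:
            raise TowmutError("pct_protective must lie in [0, 1]")
        if not 0 < self.pct_causal_of_rare <= 1:
            raise TowmutError("pct_causal_of_rare must lie in (0, 1]")


@dataclass
class HeritabilityAllocation:
    """Random partition of total heritability across traits and variants.

    ``per_trait[l] = h * t_l / sum(t)`` for uniform draws ``t_1..t_L`` and
    ``per_variant_per_trait[l, m] = per_trait[l] * r_m / sum(r)`` for uniform
    draws ``r_1..r_nc``; both partitions sum exactly by construction.
    """

    h: float
    per_trait: np.ndarray
    per_variant_per_trait: np.ndarray


@dataclass
class FactorModelSpec:
    """Parameterization of the factor-model trait generator.

    Defaults give within-factor trait correlation c^2 = 0.7 and
    between-factor correlation rho * c^2 = 0.3.
    """

    model_id: int = 1
    K: int = 10
    c: float = np.sqrt(0.7)
    rho: float = 3.0 / 7.0
    h: float = 0.0
    covariate_coefs: tuple[float, float] = (0.5, 0.5)
    binary_traits: tuple[int, ...] = ()

    def __post_init__(self):
        if self.model_id not in range(1, 7):
            raise TowmutError("model_id must be in 1..6")
        if self.model_id == 6:
            self.c = 1.0
        K = self.K
        if self.model_id in (2, 4) and K % 5:
            raise TowmutError("models 2 and 4 need K divisible by 5")
        if self.model_id in (3, 5) and K % 2:
            raise TowmutError("models 3 and 5 need K divisible by 2")
        if self.h > 0 and K < self.n_affected:
            raise TowmutError(
                f"model {self.model_id} affects {self.n_affected} traits; K too small"
            )
        if not 0 <= self.h < 1:
            raise TowmutError("heritability h must lie in [0, 1)")
        if any(k < 0 or k >= K for k in self.binary_traits):
            raise TowmutError("binary_traits indices out of range")

    @property
    def R(self) -> int:
        return self.K if self.model_id == 6 else _N_FACTORS[self.model_id]

    @property
    def n_affected(self) -> int:
        return _N_AFFECTED[self.model_id]

    @property
    def gamma(self) -> np.ndarray:
        """K-by-R block loading matrix: trait k loads on factor (k-1)//(K/R)."""
        K, R = self.K, self.R
        g = np.zeros((K, R))
        block = K // R
        g[np.arange(K), np.arange(K) // block] = 1.0
        return g


def sample_mafs(spec: GenotypeSpectrumSpec, seed_or_rng=None) -> np.ndarray:
    """Draw the M minor-allele frequencies of one synthetic super gene."""
    rng = _rng_from(spec.seed if seed_or_rng is None else seed_or_rng)
    p_common = 1.0 - spec.fraction_rare - spec.fraction_in_window
    comp = rng.choice(
        3, size=spec.M, p=[spec.fraction_rare, spec.fraction_in_window, p_common]
    )
    mafs = np.empty(spec.M)
    rare = comp == 0
    mafs[rare] = rng.uniform(spec.maf_floor, spec.rare_threshold, rare.sum())
    win = comp == 1
    mafs[win] = rng.uniform(*spec.window, win.sum())
    com = comp == 2
    mafs[com] = rng.uniform(spec.window[1], spec.common_max, com.sum())
    return mafs


def generate_genotypes(
    n: int, spec: GenotypeSpectrumSpec, seed_or_rng=None, mafs=None
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes at the spectrum's sampled frequencies.

    Each variant's dosage is Binomial(2, MAF) independently across samples.
    Pass ``mafs`` to reuse a previously sampled spectrum (one super gene,
    many replicates).
    """
    if n < 2:
        raise TowmutError("n must be >= 2")
    rng = _rng_from(spec.seed if seed_or_rng is None else seed_or_rng)
    if mafs is None:
        mafs = sample_mafs(spec, rng)
    mafs = np.asarray(mafs, dtype=float)
    values = rng.binomial(2, mafs, size=(n, mafs.size)).astype(float)
    return GenotypeMatrix(values=values, mafs=mafs)


def select_causal(gm: GenotypeMatrix, cfg: CausalConfig, seed_or_rng=None):
    """Randomly pick risk and protective variants among the rare ones.

    ``n_c = round(pct_causal_of_rare * n_rare)`` variants are drawn without
    replacement from the variants with MAF below ``rare_threshold``;
    ``n_p = round(pct_protective * n_c)`` of them are labelled protective.

    Returns ``(risk_indices, protective_indices)``.
    """
    rng = _rng_from(cfg.seed if seed_or_rng is None else seed_or_rng)
    maf = gm.maf
    rare = np.flatnonzero(maf < cfg.rare_threshold)
    n_c = int(round(cfg.pct_causal_of_rare * rare.size))
    if n_c < 1 or rare.size < n_c:
        raise TowmutError(
            f"too few rare variants ({rare.size}) to pick {n_c} causal ones"
        )
    chosen = rng.choice(rare, size=n_c, replace=False)
    n_p = int(round(cfg.pct_protective * n_c))
    n_r = n_c - n_p
    return np.sort(chosen[:n_r]), np.sort(chosen[n_r:])


def allocate_heritability(
    h: float, L: int, n_c: int, seed_or_rng=None
) -> HeritabilityAllocation:
    """Partition total heritability h over L traits, then over n_c variants.

    Proportions are normalized uniform draws, so ``sum_l h_l = h`` and
    ``sum_m h_l(m) = h_l`` hold exactly.
    """
    if not 0 <= h < 1:
        raise TowmutError("h must lie in [0, 1)")
    if L < 1 or n_c < 1:
        raise TowmutError("L and n_c must be >= 1")
    rng = _rng_from(seed_or_rng)
    t = rng.uniform(size=L)
    per_trait = h * t / t.sum()
    r = rng.uniform(size=n_c)
    per_variant = per_trait[:, None] * (r / r.sum())[None, :]
    return HeritabilityAllocation(
        h=h, per_trait=per_trait, per_variant_per_trait=per_variant
    )


def effect_sizes(alloc: HeritabilityAllocation, mafs) -> np.ndarray:
    """Per-trait, per-variant effect sizes implied by the heritability split.

    ``beta_lm = sqrt( h_l(m) / (2 p_m (1 - p_m) (1 - h_l)) )`` so that the
    genetic variance contributed by variant m to trait l, relative to the
    unit non-genetic variance of the factor-plus-residual part, equals its
    allocated heritability. Protective variants receive their minus sign at
    trait-construction time.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs >= 1):
        raise TowmutError("causal variant MAFs must lie strictly in (0, 1)")
    var_g = 2.0 * mafs * (1.0 - mafs)
    hl = alloc.per_trait[:, None]
    return np.sqrt(alloc.per_variant_per_trait / (var_g[None, :] * (1.0 - hl)))


def _factor_draw(rng, n, R, rho):
    """n draws of f ~ MVN(0, (1-rho) I + rho J), via a shared latent normal."""
    if R == 1:
        return rng.standard_normal((n, 1))
    if rho < 0:
        raise TowmutError("rho must be >= 0")
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, R))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own


def generate_traits(
    gm: GenotypeMatrix,
    spec: FactorModelSpec,
    cfg: CausalConfig | None = None,
    alloc: HeritabilityAllocation | None = None,
    seed_or_rng=None,
    return_details: bool = False,
):
    """Simulate the K traits and the two covariates for one sample.

    With ``spec.h = 0`` (the null) no genotype term enters. With positive
    heritability, causal variants are drawn per ``cfg``, heritability is
    partitioned (``alloc`` may be supplied to reuse a partition), and the
    affected traits receive the beta-weighted risk-minus-protective dosage
    sum. Traits listed in ``spec.binary_traits`` are dichotomized by the
    liability threshold.

    Returns ``(TraitMatrix, CovariateMatrix)``, plus a dict with the causal
    indices, heritability allocation and effect sizes when
    ``return_details=True``.
    """
    rng = _rng_from(seed_or_rng)
    n, K = gm.n_samples, spec.K
    z1 = rng.standard_normal(n)
    z2 = rng.binomial(1, 0.5, n).astype(float)
    a1, a2 = spec.covariate_coefs
    covar_term = a1 * z1 + a2 * z2

    lam = np.zeros((n, K))
    details = {"risk": None, "protective": None, "alloc": None, "betas": None}
    if spec.h > 0:
        if cfg is None:
            cfg = CausalConfig()
        risk, prot = select_causal(gm, cfg, rng)
        causal = np.concatenate([risk, prot])
        if alloc is None:
            alloc = allocate_heritability(spec.h, spec.n_affected, causal.size, rng)
        betas = effect_sizes(alloc, gm.maf[causal])
        signs = np.concatenate([np.ones(risk.size), -np.ones(prot.size)])
        geno = gm.values[:, causal]  # raw dosages of the causal variants
        lam[:, : spec.n_affected] = geno @ (signs[None, :] * betas).T
        details.update(risk=risk, protective=prot, alloc=alloc, betas=betas)

    f = _factor_draw(rng, n, spec.R, spec.rho)
    eps = rng.standard_normal((n, K))
    y = (
        covar_term[:, None]
        + lam
        + spec.c * f @ spec.gamma.T
        + np.sqrt(1.0 - spec.c**2) * eps
    )

    trait_types = [QUANTITATIVE] * K
    for k in spec.binary_traits:
        y[:, k] = dichotomize(y[:, k])
        trait_types[k] = BINARY
    tm = TraitMatrix(values=y, trait_types=trait_types)
    cov = CovariateMatrix(
        values=np.column_stack([z1, z2]), covariate_ids=["Z1", "Z2"]
    )
    if return_details:
        return tm, cov, details
    return tm, cov


def dichotomize(y: np.ndarray) -> np.ndarray:
    """Liability-threshold case status: 1 where y >= mean(y) + sd(y).

    On a normal trait this yields prevalence 1 - Phi(1) ~ 0.1587 (~16%).
    The sample standard deviation (ddof = 1) is used.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise TowmutError("dichotomize needs at least two values")
    sd = y.std(ddof=1)
    if sd == 0:
        raise TowmutError("cannot dichotomize a zero-variance trait")
    return (y >= y.mean() + sd).astype(float)


def binomial_ci(p: float, n_replicates: int) -> tuple[float, float]:
    """95% normal-approximation interval for a proportion p at n replicates."""
    half = 1.96 * np.sqrt(p * (1.0 - p) / n_replicates)
    return (float(p - half), float(p + half))


def _replicate_pvalues(Xr, Yr, B, rng, want_single):
    """TOWmuT (and optionally min-p) permutation p-values for one replicate.

    ``Xr``/``Yr`` are residualized (or centered) genotypes and traits. Both
    tests share one permutation stream drawn from ``rng``. Monomorphic
    columns (a routine occurrence when very rare variants miss a finite
    sample) are dropped silently here.
    """
    Xk = Xr[:, diag_scale(Xr) > _MONOMORPHIC_TOL]
    if Xk.shape[1] == 0:
        raise TowmutError("all variants are monomorphic in this replicate")
    G = _scaled_genotypes(Xk)
    L = _trait_cholesky(Yr)
    GtY = G.T @ Yr
    W = scipy.linalg.solve_triangular(L, GtY.T, lower=True).T
    obs = float(np.linalg.svd(W, compute_uv=False)[0] ** 2)
    stats, trait_stats = _permutation_statistics(
        G, Yr, B, rng, per_trait=want_single
    )
    out = {"towmut": float(np.mean(stats >= obs))}
    if want_single:
        trait_ss = np.einsum("ik,ik->k", Yr, Yr)
        obs_traits = np.einsum("mk,mk->k", GtY, GtY) / trait_ss
        out["single_tow"] = _min_p_overall(obs_traits, trait_stats)
    return out


def _run_rejection_study(
    spec, n, n_replicates, B, alpha, seed, covariates, methods, gspec, cfg
):
    if gspec is None:
        gspec = GenotypeSpectrumSpec()
    if isinstance(methods, str):
        methods = (methods,)
    want_single = "single_tow" in methods
    ss = np.random.SeedSequence(seed)
    spectrum_seed, *rep_seeds = ss.spawn(n_replicates + 1)
    mafs = sample_mafs(gspec, np.random.default_rng(spectrum_seed))
    rejections = {m: 0 for m in methods}
    for child in rep_seeds:
        rng = np.random.default_rng(child)
        gm = generate_genotypes(n, gspec, rng, mafs=mafs)
        tm, cov = generate_traits(gm, spec, cfg=cfg, seed_or_rng=rng)
        if covariates:
            Xr = residualize(gm.values, cov.values)
            Yr = residualize(tm.values, cov.values)
        else:
            Xr = centralize(gm.values)
            Yr = centralize(tm.values)
        pvals = _replicate_pvalues(Xr, Yr, B, rng, want_single)
        for m in methods:
            rejections[m] += pvals[m] <= alpha
    out = {}
    for m in methods:
        rate = rejections[m] / n_replicates
        out[m] = SimulationEstimate(
            nominal_level=alpha,
            n_replicates=n_replicates,
            rejection_rate=rate,
            ci95=binomial_ci(rate, n_replicates),
        )
    return out


def estimate_type1_error(
    spec: FactorModelSpec,
    n: int,
    n_replicates: int,
    B: int,
    alpha: float,
    seed: int,
    *,
    covariates: bool = True,
    methods="towmut",
    gspec: GenotypeSpectrumSpec | None = None,
):
    """Null rejection rate of the covariate-adjusted test.

    Data are generated under the given factor model with no genotype effect
    (``spec.h`` is ignored; the null sets every trait's genotype term to
    zero). Returns a :class:`SimulationEstimate` for a single method, or a
    dict keyed by method name when several are requested.
    """
    null_spec = FactorModelSpec(
        model_id=spec.model_id,
        K=spec.K,
        c=spec.c,
        rho=spec.rho,
        h=0.0,
        covariate_coefs=spec.covariate_coefs,
        binary_traits=spec.binary_traits,
    )
    out = _run_rejection_study(
        null_spec, n, n_replicates, B, alpha, seed, covariates, methods, gspec, None
    )
    return out[methods] if isinstance(methods, str) else out


def estimate_power(
    spec: FactorModelSpec,
    n: int,
    n_replicates: int,
    B: int,
    alpha: float,
    seed: int,
    *,
    covariates: bool = True,
    methods="towmut",
    cfg: CausalConfig | None = None,
    gspec: GenotypeSpectrumSpec | None = None,
):
    """Rejection rate under a positive-heritability alternative.

    ``spec.h`` must be > 0; causal variants, the heritability partition and
    all noise are redrawn every replicate. With ``h = 0`` this reduces to
    the type-I-error estimate.
    """
    if spec.h < 0:
        raise TowmutError("heritability must be nonnegative")
    if cfg is None:
        cfg = CausalConfig()
    out = _run_rejection_study(
        spec, n, n_replicates, B, alpha, seed, covariates, methods, gspec, cfg
    )
    return out[methods] if isinstance(methods, str) else out
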