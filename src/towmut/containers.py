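"""In-memory containers for genotypes, traits and test results.

Genotypes are stored as sample-by-variant minor-allele dosage matrices
(entries in [0, 2]; real-valued after mean imputation of missing calls).
Traits are sample-by-trait matrices in which every column is tagged either
``quantitative`` or ``binary`` (binary columns are 0/1 coded, 1 = case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import TowmutError

QUANTITATIVE = "quantitative"
BINARY = "binary"


def _as_2d_float(values, name, allow_no_columns=False):
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise TowmutError(f"{name} must be a non-empty 2-D array")
    if arr.shape[1] == 0 and not allow_no_columns:
        raise TowmutError(f"{name} must have at least one column")
    if not np.all(np.isfinite(arr)):
        raise TowmutError(f"{name} contains non-finite entries")
    return arr


@dataclass
class GenotypeMatrix:
    """Sample-by-variant minor-allele dosage matrix with variant metadata.

    Parameters
    ----------
    values : (n, M) array
        Minor-allele counts per individual and variant. Entries must lie in
        [0, 2]; fractional values are allowed (mean-imputed missing calls).
    variant_ids, sample_ids : sequences of str
        Labels for the columns and rows. Generated automatically if omitted.
    mafs : (M,) array, optional
        Population minor-allele frequencies, if known (e.g. the frequencies a
        simulation drew genotypes from). When absent, :attr:`maf` falls back
        to the sample estimate ``mean(dosage) / 2``.
    """

    values: np.ndarray
    variant_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)
    mafs: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "genotype matrix")
        n, M = self.values.shape
        if n < 2:
            raise TowmutError("at least two samples are required")
        if self.values.min() < 0 or self.values.max() > 2:
            raise TowmutError("genotype dosages must lie in [0, 2]")
        if self.variant_ids is None:
            self.variant_ids = [f"v{m + 1}" for m in range(M)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.variant_ids) != M:
            raise TowmutError("variant_ids length does not match columns")
        if len(self.sample_ids) != n:
            raise TowmutError("sample_ids length does not match rows")
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if self.mafs.shape != (M,):
                raise TowmutError("mafs length does not match variant count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequencies (stored if provided, else sample MAF)."""
        if self.mafs is not None:
            return self.mafs
        return self.values.mean(axis=0) / 2.0


@dataclass
class TraitMatrix:
    """Sample-by-trait matrix with a quantitative/binary flag per trait."""

    values: np.ndarray
    trait_types: list[str] = field(default=None)
    trait_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = _as_2d_float(self.values, "trait matrix")
        n, K = self.values.shape
        if self.trait_types is None:
            self.trait_types = [
                BINARY if set(np.unique(col)) <= {0.0, 1.0} else QUANTITATIVE
                for col in self.values.T
            ]
        self.trait_types = list(self.trait_types)
        if len(self.trait_types) != K:
            raise TowmutError("trait_types length does not match columns")
        for k, t in enumerate(self.trait_types):
            if t not in (QUANTITATIVE, BINARY):
                raise TowmutError(f"unknown trait type {t!r}")
            if t == BINARY and not set(np.unique(self.values[:, k])) <= {0.0, 1.0}:
                raise TowmutError(
                    f"binary trait column {k} contains values outside {{0, 1}}"
                )
        if self.trait_ids is None:
            self.trait_ids = [f"y{k + 1}" for k in range(K)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        self.trait_ids = [str(t) for t in self.trait_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def has_binary(self) -> bool:
        return BINARY in self.trait_types


@dataclass
class CovariateMatrix:
    """Sample-by-covariate matrix. The intercept is NOT stored; test
    routines always augment the design with a leading column of ones."""

    values: np.ndarray
    covariate_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        # a zero-column matrix is a valid "no covariates" placeholder
        self.values = _as_2d_float(self.values, "covariate matrix", allow_no_columns=True)
        n, p = self.values.shape
        if self.covariate_ids is None:
            self.covariate_ids = [f"z{j + 1}" for j in range(p)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        self.covariate_ids = [str(c) for c in self.covariate_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]


@dataclass
class WeightVector:
    """Variant weights; the optimal weights are defined up to scale."""

    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.w.size == 0 or not np.all(np.isfinite(self.w)):
            raise TowmutError("weights must be a non-empty finite vector")


@dataclass
class RegionTestResult:
    """Outcome of a permutation-based region test."""

    statistic: float
    p_value: float
    n_permutations: int
    optimal_weights: WeightVector
    method: str
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise TowmutError("p-value outside [0, 1]")


@dataclass
class ManovaResult:
    """Wilks' lambda likelihood-ratio test of a multivariate regression."""

    wilks_lambda: float
    statistic: float
    df: int
    p_value: float


@dataclass
class SingleTowResult:
    """Per-trait TOW tests combined through the minimum permutation p-value."""

    per_trait_pvalues: np.ndarray
    statistic: float  # the observed min p over traits
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class SimulationEstimate:
    """A Monte-Carlo rejection proportion with its 95% normal-approximation CI."""

    nominal_level: float
    n_replicates: int
    rejection_rate: float
    ci95: tuple[float, float]
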