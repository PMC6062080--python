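"""File input/output, fixed-width block scanning and report writing.

Supported formats
-----------------
* VCF (input): biallelic records become minor-allele dosage columns;
  multiallelic records are skipped with a warning; missing calls are
  mean-imputed. Dosages are re-oriented so they always count the
  within-sample minor allele (flipped when the ALT frequency exceeds 0.5).
* Tab-delimited dosage matrix (input/output): samples in rows, variants in
  columns, first column holds sample ids.
* Tab-delimited phenotype/covariate tables: header plus a sample-id first
  column.
* Reports: tab-delimited per-block table plus a JSON summary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .compare import manova_wilks, single_tow
from .containers import (
    BINARY,
    CovariateMatrix,
    GenotypeMatrix,
    TraitMatrix,
)
from .covariates import towmut_with_covariates
from .exceptions import TowmutError

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotype_matrix",
    "write_vcf",
    "read_traits",
    "read_covariates",
    "make_blocks",
    "scan",
    "RegionDefinition",
    "ScanReport",
    "load_sim_config",
]


@dataclass
class RegionDefinition:
    """A testable region: either a genomic interval (0-based half-open) or a
    consecutive block of variants under fixed-width blocking."""

    block_index: int
    start: int  # first variant index (inclusive)
    stop: int  # past-the-end variant index
    chrom: str | None = None
    pos_start: int | None = None
    pos_end: int | None = None

    @property
    def label(self) -> str:
        if self.chrom is not None:
            return f"{self.chrom}:{self.pos_start}-{self.pos_end}"
        return f"block{self.block_index + 1}"


@dataclass
class ScanReport:
    """Per-region test results with a Bonferroni family-wise threshold."""

    table: pd.DataFrame
    bonferroni_alpha: float
    n_blocks: int
    methods: tuple[str, ...]
    correction: str = "bonferroni"

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path):
        payload = {
            "n_blocks": self.n_blocks,
            "bonferroni_alpha": self.bonferroni_alpha,
            "correction": self.correction,
            "methods": list(self.methods),
            "blocks": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _flip_to_minor(dosages: np.ndarray, variant_ids: list[str]):
    """Re-orient dosage columns so they count the minor allele."""
    freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        flipped = [variant_ids[m] for m in np.flatnonzero(flip)]
        logger.info(
            "flipped %d variant(s) where ALT is the major allele: %s",
            len(flipped),
            flipped[:10],
        )
        dosages[:, flip] = 2.0 - dosages[:, flip]
    return dosages


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids = [], []
    n_multi = 0
    for record in vcf:
        if len(record.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(record.genotypes, dtype=object)
        dose = np.empty(len(samples))
        for i, gt in enumerate(gts):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            dose[i] = np.nan if not alleles else float(sum(a > 0 for a in alleles))
        cols.append(dose)
        vid = record.ID if record.ID not in (None, ".") else (
            f"{record.CHROM}:{record.POS}"
        )
        ids.append(vid)
    vcf.close()
    if n_multi:
        warnings.warn(
            f"skipped {n_multi} multiallelic record(s)", UserWarning, stacklevel=3
        )
    if not cols:
        raise TowmutError(f"no usable biallelic records in {path}")
    dosages = np.column_stack(cols)
    dosages = _flip_to_minor(dosages, ids)
    # mean-impute missing calls per variant
    missing = np.isnan(dosages)
    if missing.any():
        col_mean = np.where(
            missing.all(axis=0), 0.0, np.nanmean(dosages, axis=0)
        )
        dosages[missing] = np.broadcast_to(col_mean, dosages.shape)[missing]
        logger.warning("mean-imputed %d missing genotype call(s)", missing.sum())
    return GenotypeMatrix(values=dosages, variant_ids=ids, sample_ids=samples)


def _read_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    missing = np.isnan(values)
    if missing.any():
        col_mean = np.where(missing.all(axis=0), 0.0, np.nanmean(values, axis=0))
        values[missing] = np.broadcast_to(col_mean, values.shape)[missing]
        logger.warning("mean-imputed %d missing dosage entr(ies)", missing.sum())
    values = _flip_to_minor(values, list(df.columns))
    return GenotypeMatrix(
        values=values,
        variant_ids=list(df.columns),
        sample_ids=[str(s) for s in df.index],
    )


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Load genotypes from a VCF or a tab-delimited dosage matrix.

    ``format`` may be ``"vcf"``, ``"matrix"`` or ``"auto"`` (by extension).
    Dosages are always oriented to count the minor allele.
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "matrix"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise TowmutError(f"unknown genotype format {format!r}")


def write_genotype_matrix(gm: GenotypeMatrix, path):
    """Tab-delimited dosage matrix; round-trips losslessly via read_genotypes."""
    df = pd.DataFrame(gm.values, index=gm.sample_ids, columns=gm.variant_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_vcf(gm: GenotypeMatrix, path, chrom: str = "1"):
    """Write integer dosages as a minimal diploid VCF (REF=A, ALT=T).

    Fractional (imputed) dosages cannot be represented and raise an error.
    """
    vals = gm.values
    if not np.allclose(vals, np.round(vals)):
        raise TowmutError("VCF output requires integer dosages")
    ivals = np.round(vals).astype(int)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for m, vid in enumerate(gm.variant_ids):
            gts = "\t".join(gt_map[g] for g in ivals[:, m])
            fh.write(f"{chrom}\t{m + 1}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def _read_table(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_traits(path, trait_types=None) -> TraitMatrix:
    """Phenotype table: header row, sample ids in the first column.

    Trait types are inferred (a column whose values are all 0/1 is binary)
    unless given explicitly.
    """
    df = _read_table(path)
    return TraitMatrix(
        values=df.to_numpy(dtype=float),
        trait_types=trait_types,
        trait_ids=list(df.columns),
        sample_ids=[str(s) for s in df.index],
    )


def read_covariates(path) -> CovariateMatrix:
    df = _read_table(path)
    return CovariateMatrix(
        values=df.to_numpy(dtype=float),
        covariate_ids=list(df.columns),
        sample_ids=[str(s) for s in df.index],
    )


def make_blocks(n_snps: int, width: int = 50) -> list[RegionDefinition]:
    """Consecutive non-overlapping variant blocks; the last may be short.

    The number of blocks is ``ceil(n_snps / width)``.
    """
    if width < 1:
        raise TowmutError("block width must be >= 1")
    if n_snps < 1:
        raise TowmutError("n_snps must be >= 1")
    blocks = []
    for b, start in enumerate(range(0, n_snps, width)):
        blocks.append(
            RegionDefinition(block_index=b, start=start, stop=min(start + width, n_snps))
        )
    return blocks


def _align_samples(gm: GenotypeMatrix, tm: TraitMatrix, cov: CovariateMatrix | None):
    """Inner-join the three tables on sample id, preserving genotype order."""
    trait_pos = {s: i for i, s in enumerate(tm.sample_ids)}
    cov_pos = (
        {s: i for i, s in enumerate(cov.sample_ids)} if cov is not None else None
    )
    keep, t_idx, c_idx = [], [], []
    for i, s in enumerate(gm.sample_ids):
        if s not in trait_pos:
            continue
        if cov_pos is not None and s not in cov_pos:
            continue
        keep.append(i)
        t_idx.append(trait_pos[s])
        if cov_pos is not None:
            c_idx.append(cov_pos[s])
    n_dropped = gm.n_samples - len(keep)
    if n_dropped:
        logger.warning(
            "dropped %d sample(s) absent from the phenotype/covariate tables",
            n_dropped,
        )
    if len(keep) < 2:
        raise TowmutError("fewer than two samples shared across input files")
    # sort by sample id for an order-invariant result
    order = np.argsort([gm.sample_ids[i] for i in keep], kind="stable")
    keep = np.asarray(keep)[order]
    t_idx = np.asarray(t_idx)[order]
    X = gm.values[keep]
    Y = tm.values[t_idx]
    Z = cov.values[np.asarray(c_idx)[order]] if cov is not None else None
    return X, Y, Z


def scan(
    gm: GenotypeMatrix,
    tm: TraitMatrix,
    covariates: CovariateMatrix | None = None,
    methods=("towmut",),
    B: int = 1000,
    seed: int = 1,
    block_size: int = 50,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> ScanReport:
    """Test every fixed-width variant block against the traits.

    Samples are aligned by id across the three inputs (inner join; drops are
    logged). The family-wise threshold is ``alpha / n_blocks`` (Bonferroni);
    ``correction="bh"`` additionally flags blocks by Benjamini-Hochberg.
    Blocks in which every variant is monomorphic are reported as untestable
    (NaN statistics) rather than aborting the scan.
    """
    if isinstance(methods, str):
        methods = tuple(s.strip() for s in methods.split(","))
    known = {"towmut", "manova", "single-tow"}
    unknown = set(methods) - known
    if unknown:
        raise TowmutError(f"unknown method(s): {sorted(unknown)}")
    X_all, Y_all, Z = _align_samples(gm, tm, covariates)
    if Z is not None and Z.shape[1] == 0:
        Z = None
    blocks = make_blocks(gm.n_variants, block_size)
    threshold = alpha / len(blocks)
    ss = np.random.SeedSequence(seed)
    block_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(blocks))]
    rows = []
    for region, bseed in zip(blocks, block_seeds):
        Xb = X_all[:, region.start : region.stop]
        Xb = Xb[:, Xb.std(axis=0) > 0]  # monomorphic variants carry no signal
        row = {
            "region": region.label,
            "start": region.start,
            "stop": region.stop,
            "n_variants": region.stop - region.start,
        }
        testable = np.any(Xb.std(axis=0) > 0)
        for method in methods:
            if not testable:
                row[f"{method}_statistic"] = np.nan
                row[f"{method}_p"] = np.nan
                continue
            try:
                if method == "towmut":
                    res = towmut_with_covariates(Xb, Y_all, Z, B, bseed)
                    row["towmut_statistic"] = res.statistic
                    row["towmut_p"] = res.p_value
                elif method == "manova":
                    res = manova_wilks(Xb, Y_all, trait_types=tm.trait_types)
                    row["manova_statistic"] = res.statistic
                    row["manova_p"] = res.p_value
                elif method == "single-tow":
                    res = single_tow(Xb, Y_all, B, bseed)
                    row["single-tow_statistic"] = res.statistic
                    row["single-tow_p"] = res.p_value
            except TowmutError as err:
                logger.warning("%s failed on %s: %s", method, region.label, err)
                row[f"{method}_statistic"] = np.nan
                row[f"{method}_p"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    pcols = [f"{m}_p" for m in methods]
    table["significant"] = (table[pcols] <= threshold).any(axis=1)
    if correction == "bh":
        from scipy.stats import false_discovery_control

        for m in methods:
            p = table[f"{m}_p"].to_numpy()
            ok = np.isfinite(p)
            q = np.full_like(p, np.nan)
            if ok.any():
                q[ok] = false_discovery_control(p[ok])
            table[f"{m}_q"] = q
    elif correction != "bonferroni":
        raise TowmutError("correction must be 'bonferroni' or 'bh'")
    return ScanReport(
        table=table,
        bonferroni_alpha=threshold,
        n_blocks=len(blocks),
        methods=tuple(methods),
        correction=correction,
    )


def load_sim_config(path) -> dict:
    """Declarative simulation configuration (YAML).

    Recognized keys: model_id, n, K, h, c, rho, pct_causal, pct_protective,
    n_replicates, B, alpha, seed, binary_traits, covariates.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TowmutError("simulation config must be a YAML mapping")
    return cfg
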