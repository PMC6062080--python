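# Methods

## The statistic

The test targets association between a genomic region's `M` variants and
`K` possibly correlated traits by scoring a weighted allele burden
`x_i = Σ_m w_m x_im` against the traits in a reverse regression: the burden
is the response, the centered traits are the predictors. For fixed weights
the score test of "all trait coefficients zero" is `UᵀV⁻¹U/σ²` with
`U = YᵀXw`, `V = YᵀY` and `σ² = wᵀXᵀXw/n`; replacing `XᵀX/n` by its
diagonal `A` (the usual simplification that makes the maximization
tractable and stabilizes the denominator for rare variants) gives the
Rayleigh-type ratio

    T(w) = wᵀXᵀY (YᵀY)⁻¹ YᵀXw / (wᵀAw),

whose maximum over `w` is the largest eigenvalue of
`A^{-1/2}XᵀY(YᵀY)⁻¹YᵀXA^{-1/2}` — equivalently of `(YᵀY)⁻¹YᵀCY` with
`C = XA⁻¹Xᵀ`. Because the statistic maximizes over all weight directions it
is insensitive to the sign of individual variant effects (risk vs
protective) and to per-variant rescaling, and it is invariant under any
invertible linear recoding of the traits.

Numerically the package never forms the nonsymmetric `K×K` product:
with `G = X A^{-1/2}` and a Cholesky factor `YᵀY = LLᵀ`, the statistic is
the largest squared singular value of `GᵀY L^{-T}`, a symmetric-PSD
computation that cannot produce spurious negative or complex eigenvalues.
The nonsymmetric form and a direct multistart numerical maximization of
`T(w)` serve as independent cross-checks in the test suite.

## Permutation inference

P-values come from jointly permuting the rows of the trait matrix —
each individual's K trait values travel together, so the trait correlation
structure is preserved under the null. `C` (through `G`) and `(YᵀY)⁻¹` are
permutation-invariant and computed once. The reported p-value is
`#{permuted T ≥ observed T}/B`, which lives on the grid `{0, 1/B, …, 1}`
and can be exactly zero; a `plus_one` option gives the strictly positive
`(1+#)/(1+B)` variant for users who need valid p-values. Ties count as
exceedances.

Permutations are evaluated in batches: the permuted trait blocks are
stacked into one `(B·K) × n` matrix so the dominant cost is a single
BLAS matrix product per batch, followed by batched `K×K` eigensolves.
The batch partition is a fixed function of `(B, n)`, so the permutation
stream — produced by `numpy`'s PCG64 generator via `rng.permuted` — is a
pure function of `(seed, B, n)` and results are independent of memory
batching.

## Covariates

Both traits and genotypes are residualized on `[1 | Z]` (the intercept is
always included) by OLS through a thin QR decomposition, and the
unadjusted test is applied to the residuals. Binary traits are residualized
by the same linear model as quantitative ones — a deliberate choice that
keeps the adjusted statistic identical to the score statistic of the joint
linear model (shown via the explicit projector `P = D(DᵀD)⁻¹Dᵀ` and the
idempotence of `I−P`); whether a logistic residual would alter calibration
is untested here. Rank-deficient covariate designs raise a named error
rather than silently pseudo-inverting.

## Comparison tests

* **MANOVA.** `Y = Xβ + ε` fitted by least squares;
  `−n·log(|E|/|E+H|)` with `H = β̂ᵀ(XᵀX)β̂`, `E = YᵀY − H`, referred to a
  χ² distribution. The default degrees of freedom are `M·K` (the number of
  constrained coefficients); `df="k"` selects a χ²_K reference instead.
  Both are exposed because the two are materially different for `M > 1`
  and published practice is ambiguous; the default favours the standard
  likelihood-ratio count. MANOVA emits a warning when binary traits are
  present (its normal likelihood is then misspecified and the reference
  can be anticonservative).
* **Per-trait min-p ("single-TOW").** Each trait is tested with the K=1
  statistic `(yᵀCy)/(yᵀy)`; all traits share one permutation stream, each
  permuted statistic is converted to a p-value by its descending rank
  among the B permutations, and the observed minimum p is referred to the
  permutation distribution of per-permutation minima. Sharing the stream
  is what makes the min-p null coherent.

## Synthetic data generator

The generator reproduces the validation study's conditions:

* **Genotypes.** `M = 100` variants per region. MAFs are drawn from a
  three-part mixture — 90% rare, uniform on (0.0007, 0.01), where 0.0007 ≈
  1/(2·697) is the smallest frequency observable in a 697-individual
  reference panel; 8% in the low-frequency window (0.01, 0.035); 2% common
  on (0.035, 0.5) — and genotypes are Binomial(2, MAF) per individual
  (Hardy–Weinberg, independent variants). One spectrum is sampled per
  study and genotypes are redrawn every replicate.
* **Traits.** `y = (0.5·Z1 + 0.5·Z2)·1 + λ + c·γf + √(1−c²)·ε` with
  `Z1 ~ N(0,1)`, `Z2 ~ Bernoulli(0.5)`, factors
  `f ~ MVN(0, (1−ρ)I + ρJ)` and block 0/1 loadings `γ`. Defaults
  `c = √0.7`, `ρ = 3/7` give within-factor trait correlation 0.7 and
  between-factor correlation 0.3. Six layouts vary the factor count
  (1, 5, 2, 5, 2, K) and whether genotypes act on six traits or one;
  layout 6 fixes `c = 1` (pure independent factors). Block sizes require
  `K` divisible by 5 (layouts 2, 4) or 2 (layouts 3, 5); `K = 10` makes
  everything well defined.
* **Causal architecture.** All causal variants are rare (MAF < 0.01);
  `n_c = round(0.2 · n_rare)` of them are drawn per replicate, a
  configurable fraction flagged protective (negative sign). Total
  heritability `h` is split over the affected traits by normalized uniform
  draws (`h_l = h·t_l/Σt`), then over causal variants the same way; both
  partitions sum exactly. Effect sizes are
  `β_lm = √( h_l(m) / (2p_m(1−p_m)(1−h_l)) )`, which makes the genetic
  variance of trait `l` relative to its unit-variance factor+residual part
  equal `h_l/(1−h_l)` — i.e. heritability is defined *excluding* the
  covariate variance (0.3125 under the defaults). The recovery test
  therefore checks the partial R² after removing covariates.
* **Binary traits.** Liability thresholding at `mean + 1·sd` (sample sd,
  ddof = 1), prevalence `1 − Φ(1) ≈ 0.1587` on normal traits.

What the generator deliberately does **not** emulate: linkage
disequilibrium between variants (real exome genotypes are correlated;
here variants are independent given their MAFs), population structure or
relatedness, genotyping error, and non-normal trait residuals. Passing
calibration here shows the test's permutation machinery is correct under
exchangeability; it does not by itself establish robustness to structure
or LD.

## Monte-Carlo harnesses and problem sizes

Type-I error: null data (`λ = 0`), rejection fraction of `p ≤ α` with a
95% normal-approximation CI. Power: the same with `h > 0`, causal sets and
partitions redrawn per replicate. Both harnesses derive every replicate's
randomness from one master seed via `SeedSequence` spawning, so any table
cell is reproducible in isolation. The packaged calibration runs use
n = 1000 individuals, B = 1000 permutations and 1000 replicates per
condition (~0.2 s per replicate), and the power sweep uses 500 replicates
per heritability point; these sizes put the Monte-Carlo standard error of
a 5% rejection rate at ~0.7 percentage points, small enough to detect
meaningful miscalibration while keeping a full study in minutes on one
CPU.

## Numerical choices and edge cases

* Monomorphic (zero-variance) variants are dropped — `A⁻¹` requires
  strictly positive diagonals and a constant column carries no
  information; user-facing entry points log a warning, the harness drops
  silently (rare variants missing from a finite sample are routine). The
  threshold on the residualized mean square is 1e-10, orders of magnitude
  below the ≥ 1/n variance of any truly polymorphic column.
* Missing genotypes are mean-imputed per variant before centering, with
  the imputation count logged.
* Collinear traits or covariates raise named errors (offending trait
  columns identified via pivoted QR) instead of producing unstable
  pseudo-inverse results.
* Dosages read from VCF or matrix files are re-oriented to count the
  minor allele (columns with ALT frequency > 0.5 are flipped), because the
  statistic is defined on minor-allele counts. Multiallelic VCF records
  are skipped with a warning.
* Fixed-width blocking uses the ceiling rule: `ceil(n_snps/width)` blocks,
  the last possibly short. The family-wise threshold is `α/n_blocks`
  (Bonferroni); Benjamini–Hochberg q-values are available as an option.
* The observed statistic is compared to permuted ones with `≥` exactly;
  no adaptive early stopping of permutations is performed — `B` is under
  user control.

## Known limitations

* Only permutation p-values are provided for the main test (no asymptotic
  reference), so very small p-values require large `B`.
* The linear residualization of binary traits, while exact for the score
  construction, leaves open how a logistic adjustment would behave.
* MANOVA's χ² reference is asymptotic; for `M` approaching `n` it is
  unreliable, and the implementation refuses rank-deficient designs rather
  than regularizing.
* The generator's independence of variants means power results should be
  read as statements about the weighting scheme, not about LD fine-mapping.
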