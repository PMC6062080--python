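"""The synthetic data generator and the Monte-Carlo harnesses."""

import numpy as np
import pytest

from towmut import (
    CausalConfig,
    FactorModelSpec,
    GenotypeSpectrumSpec,
    TowmutError,
    allocate_heritability,
    binomial_ci,
    dichotomize,
    effect_sizes,
    estimate_power,
    estimate_type1_error,
    generate_genotypes,
    generate_traits,
    select_causal,
)
from towmut.simulate import sample_mafs


class TestGenotypes:
    def test_hardy_weinberg_moments_at_common_maf(self):
        rng = np.random.default_rng(1)
        spec = GenotypeSpectrumSpec(M=1)
        gm = generate_genotypes(20000, spec, rng, mafs=[0.5])
        col = gm.values[:, 0]
        assert col.mean() == pytest.approx(1.0, abs=0.02)
        assert col.var() == pytest.approx(0.5, abs=0.02)

    def test_zero_maf_gives_monomorphic_column(self):
        gm = generate_genotypes(50, GenotypeSpectrumSpec(M=1), 2, mafs=[0.0])
        assert np.all(gm.values == 0)

    def test_spectrum_calibration(self):
        """Across many super genes, ~8% of variants land in the
        low-frequency window (0.01, 0.035) and the bulk is rare."""
        rng = np.random.default_rng(3)
        spec = GenotypeSpectrumSpec()
        fracs, rare_fracs = [], []
        for _ in range(200):
            mafs = sample_mafs(spec, rng)
            fracs.append(np.mean((mafs > 0.01) & (mafs < 0.035)))
            rare_fracs.append(np.mean(mafs < 0.01))
        assert abs(np.mean(fracs) - 0.08) < 0.03
        assert np.mean(rare_fracs) > 0.8

    def test_dosages_in_range_and_metadata(self):
        gm = generate_genotypes(100, GenotypeSpectrumSpec(M=25), 4)
        assert gm.values.shape == (100, 25)
        assert gm.values.min() >= 0 and gm.values.max() <= 2
        assert gm.maf.shape == (25,)


class TestCausalSelection:
    def _gm(self, seed=5):
        return generate_genotypes(200, GenotypeSpectrumSpec(), seed)

    def test_counts_and_rarity(self):
        gm = self._gm()
        cfg = CausalConfig(pct_causal_of_rare=0.2, pct_protective=0.25)
        risk, prot = select_causal(gm, cfg, 7)
        n_rare = int((gm.maf < 0.01).sum())
        n_c = round(0.2 * n_rare)
        assert len(risk) + len(prot) == n_c
        assert len(prot) == round(0.25 * n_c)
        assert set(risk).isdisjoint(prot)
        assert np.all(gm.maf[np.concatenate([risk, prot])] < 0.01)

    def test_rounding_rule(self):
        """20% causal among 90 rare variants selects 18."""
        mafs = np.concatenate([np.full(90, 0.005), np.full(10, 0.2)])
        gm = generate_genotypes(100, GenotypeSpectrumSpec(), 8, mafs=mafs)
        risk, prot = select_causal(gm, CausalConfig(), 9)
        assert len(risk) + len(prot) == 18

    def test_all_risk_when_no_protective(self):
        gm = self._gm()
        risk, prot = select_causal(gm, CausalConfig(pct_protective=0.0), 10)
        assert len(prot) == 0 and len(risk) > 0

    def test_deterministic_under_seed(self):
        gm = self._gm()
        a = select_causal(gm, CausalConfig(), 11)
        b = select_causal(gm, CausalConfig(), 11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_too_few_rare_variants(self):
        mafs = np.full(10, 0.3)  # nothing rare
        gm = generate_genotypes(50, GenotypeSpectrumSpec(M=10), 12, mafs=mafs)
        with pytest.raises(TowmutError, match="rare"):
            select_causal(gm, CausalConfig(), 13)


class TestHeritability:
    def test_partitions_sum_exactly(self):
        alloc = allocate_heritability(0.08, L=6, n_c=18, seed_or_rng=1)
        assert alloc.per_trait.sum() == pytest.approx(0.08, rel=1e-12)
        np.testing.assert_allclose(
            alloc.per_variant_per_trait.sum(axis=1), alloc.per_trait, rtol=1e-12
        )

    def test_single_trait_takes_all(self):
        alloc = allocate_heritability(0.1, L=1, n_c=5, seed_or_rng=2)
        assert alloc.per_trait[0] == pytest.approx(0.1)

    def test_mean_share_is_one_over_L(self):
        """Normalized uniform proportions average 1/L per trait."""
        rng = np.random.default_rng(3)
        shares = np.array(
            [allocate_heritability(1e-9, 4, 3, rng).per_trait / 1e-9 for _ in range(2000)]
        )
        np.testing.assert_allclose(shares.mean(axis=0), 0.25, atol=0.02)

    def test_effect_size_functional_form(self):
        alloc = allocate_heritability(0.05, L=2, n_c=3, seed_or_rng=4)
        mafs = np.array([0.005, 0.008, 0.002])
        beta = effect_sizes(alloc, mafs)
        assert beta.shape == (2, 3)
        # doubling the allocated heritability multiplies beta by sqrt(2)
        alloc2 = allocate_heritability(0.05, L=2, n_c=3, seed_or_rng=4)
        alloc2.per_variant_per_trait = 2 * alloc.per_variant_per_trait
        np.testing.assert_allclose(
            effect_sizes(alloc2, mafs), np.sqrt(2) * beta, rtol=1e-12
        )
        # zero allocation -> zero effect
        alloc2.per_variant_per_trait[:] = 0
        assert np.all(effect_sizes(alloc2, mafs) == 0)

    def test_invalid_maf_rejected(self):
        alloc = allocate_heritability(0.05, L=1, n_c=2, seed_or_rng=5)
        with pytest.raises(TowmutError):
            effect_sizes(alloc, np.array([0.0, 0.5]))


class TestTraitModel:
    def test_correlation_structure_under_null(self):
        """Within-factor pairs correlate at ~c^2, across-factor at ~rho c^2."""
        rng = np.random.default_rng(6)
        gm = generate_genotypes(20000, GenotypeSpectrumSpec(M=5), rng)
        spec = FactorModelSpec(model_id=3, K=10)  # two factors, traits 1-5 / 6-10
        tm, cov = generate_traits(gm, spec, seed_or_rng=rng)
        from towmut import residualize

        # regress out the shared covariate term so the factor structure shows
        resid = residualize(tm.values, cov.values)
        corr = np.corrcoef(resid.T)
        within = [corr[i, j] for i in range(5) for j in range(i + 1, 5)]
        across = [corr[i, j] for i in range(5) for j in range(5, 10)]
        assert np.mean(within) == pytest.approx(0.7, abs=0.02)
        assert np.mean(across) == pytest.approx(0.3, abs=0.02)

    def test_c_zero_gives_independent_traits(self):
        rng = np.random.default_rng(7)
        gm = generate_genotypes(8000, GenotypeSpectrumSpec(M=5), rng)
        spec = FactorModelSpec(model_id=1, K=4, c=0.0)
        tm, cov = generate_traits(gm, spec, seed_or_rng=rng)
        from towmut import residualize

        resid = residualize(tm.values, cov.values)
        corr = np.corrcoef(resid.T)
        off = corr[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_model6_forces_unit_loading(self):
        spec = FactorModelSpec(model_id=6, K=10, c=0.3)
        assert spec.c == 1.0 and spec.R == 10
        np.testing.assert_array_equal(spec.gamma, np.eye(10))

    def test_block_structure_of_gamma(self):
        spec = FactorModelSpec(model_id=2, K=10)
        g = spec.gamma
        assert g.shape == (10, 5)
        np.testing.assert_array_equal(g.sum(axis=1), np.ones(10))
        # traits 1-2 load on factor 1, traits 3-4 on factor 2, ...
        assert g[0, 0] == g[1, 0] == 1 and g[2, 1] == g[3, 1] == 1

    def test_indivisible_K_rejected(self):
        with pytest.raises(TowmutError, match="divisible"):
            FactorModelSpec(model_id=2, K=7)

    def test_binary_traits_flagged_and_binary(self):
        rng = np.random.default_rng(8)
        gm = generate_genotypes(500, GenotypeSpectrumSpec(M=5), rng)
        spec = FactorModelSpec(model_id=1, K=10, binary_traits=(5, 6, 7, 8, 9))
        tm, _ = generate_traits(gm, spec, seed_or_rng=rng)
        assert tm.trait_types[:5] == ["quantitative"] * 5
        assert tm.trait_types[5:] == ["binary"] * 5
        assert set(np.unique(tm.values[:, 5:])) <= {0.0, 1.0}


class TestDichotomize:
    def test_four_point_example(self):
        out = dichotomize(np.array([0.0, 0.0, 0.0, 10.0]))
        np.testing.assert_array_equal(out, [0, 0, 0, 1])

    def test_location_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(500)
        np.testing.assert_array_equal(dichotomize(y), dichotomize(y + 37.5))

    def test_normal_prevalence(self):
        rng = np.random.default_rng(10)
        frac = dichotomize(rng.standard_normal(200000)).mean()
        assert frac == pytest.approx(0.1587, abs=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(TowmutError):
            dichotomize(np.ones(10))


class TestHarnesses:
    def test_binomial_ci_formula(self):
        lo, hi = binomial_ci(0.5, 100)
        assert (lo, hi) == pytest.approx((0.402, 0.598), abs=1e-3)

    def test_alpha_one_rejects_everything(self):
        spec = FactorModelSpec(model_id=1)
        est = estimate_type1_error(spec, n=120, n_replicates=10, B=20, alpha=1.0, seed=1)
        assert est.rejection_rate == 1.0

    def test_alpha_zero_rarely_rejects(self):
        """p = 0 requires the observed statistic to beat all permutations."""
        spec = FactorModelSpec(model_id=1)
        est = estimate_type1_error(spec, n=120, n_replicates=30, B=50, alpha=0.0, seed=2)
        assert est.rejection_rate <= 0.1

    def test_estimate_fields_and_reproducibility(self):
        spec = FactorModelSpec(model_id=2)
        a = estimate_type1_error(spec, n=150, n_replicates=20, B=50, alpha=0.05, seed=3)
        b = estimate_type1_error(spec, n=150, n_replicates=20, B=50, alpha=0.05, seed=3)
        assert a.rejection_rate == b.rejection_rate
        assert a.ci95[0] <= a.rejection_rate <= a.ci95[1]
        assert a.n_replicates == 20

    def test_power_exceeds_null_rate(self):
        """A strong genetic effect is detected far above the nominal level."""
        spec = FactorModelSpec(model_id=1, h=0.3)
        est = estimate_power(spec, n=400, n_replicates=25, B=100, alpha=0.05, seed=4)
        assert est.rejection_rate > 0.5

    def test_joint_methods_share_replicates(self):
        spec = FactorModelSpec(model_id=1, h=0.2)
        out = estimate_power(
            spec, n=200, n_replicates=10, B=50, alpha=0.05, seed=5,
            methods=("towmut", "single_tow"),
        )
        assert set(out) == {"towmut", "single_tow"}
        assert all(0 <= e.rejection_rate <= 1 for e in out.values())

    def test_heritability_recovery_small(self):
        """Partial R^2 of the affected trait on its causal variants tracks
        the allocated per-trait heritability (reduced-scale check)."""
        rng = np.random.default_rng(11)
        spec = FactorModelSpec(model_id=4, h=0.2)
        gm = generate_genotypes(6000, GenotypeSpectrumSpec(), rng)
        tm, cov = generate_traits(gm, spec, cfg=CausalConfig(), seed_or_rng=rng)
        # the causal set is a subset of the rare variants, so regressing on
        # all rare variants captures the full genetic variance
        from towmut import residualize

        yr = residualize(tm.values[:, [0]], cov.values).ravel()
        Xr = residualize(gm.values[:, gm.maf < 0.01], cov.values)
        coef, *_ = np.linalg.lstsq(Xr, yr, rcond=None)
        r2 = 1 - np.sum((yr - Xr @ coef) ** 2) / np.sum(yr**2)
        assert r2 == pytest.approx(0.2, abs=0.06)
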