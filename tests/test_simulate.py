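"""Generator correctness: moments, heritability bookkeeping, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xdosage as xd
from xdosage.simulate import X_NONPAR


def enumerated_variance_ratio(p: float, d: float) -> float:
    """Brute-force male/female genetic-variance ratio at one locus.

    Enumerates female genotype probabilities {(1-p)^2, 2p(1-p), p^2} with
    values {0, b_f, 2 b_f} and male haplotype probabilities {1-p, p} with
    values {0, d b_f}.
    """
    b_f = 0.37  # arbitrary nonzero effect; cancels in the ratio
    fg = np.array([0.0, b_f, 2 * b_f])
    fp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    mg = np.array([0.0, d * b_f])
    mp = np.array([1 - p, p])
    vf = fp @ fg**2 - (fp @ fg) ** 2
    vm = mp @ mg**2 - (mp @ mg) ** 2
    return vm / vf


class TestAlleleFrequencies:
    def test_degenerate_range_returns_constant(self):
        assert np.allclose(xd.draw_allele_frequencies(5, (0.5, 0.5), seed=0), 0.5)

    def test_seed_determinism_and_divergence(self):
        a = xd.draw_allele_frequencies(1000, (0.01, 0.5), seed=3)
        b = xd.draw_allele_frequencies(1000, (0.01, 0.5), seed=3)
        c = xd.draw_allele_frequencies(1000, (0.01, 0.5), seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_maf_floor_respected(self):
        p = xd.draw_allele_frequencies(10_000, (0.01, 0.5), seed=1)
        assert np.minimum(p, 1 - p).min() >= 0.01

    @pytest.mark.parametrize("bad", [(0, 0.5), (0.2, 0.1), (0.1, 0.6)])
    def test_invalid_range_rejected(self, bad):
        with pytest.raises(ValueError, match="MAF range"):
            xd.draw_allele_frequencies(10, bad, seed=0)


class TestGenotypes:
    def test_ploidy_moments(self):
        p = np.full(50, 0.5)
        G = xd.simulate_genotypes(p, 10_000, 10_000, X_NONPAR, seed=0)
        male = G.dosages[G.is_male]
        female = G.dosages[G.is_female]
        # binomial means: p for haploid males, 2p for diploid females
        se_m = np.sqrt(0.25 / 10_000)
        se_f = np.sqrt(0.5 / 10_000)
        assert np.all(np.abs(male.mean(axis=0) - 0.5) < 5 * se_m)
        assert np.all(np.abs(female.mean(axis=0) - 1.0) < 5 * se_f)
        # binomial variances p(1-p) and 2p(1-p): female/male ratio -> 2
        ratio = female.var(axis=0).mean() / male.var(axis=0).mean()
        assert ratio == pytest.approx(2.0, rel=0.03)

    def test_near_fixation_limit(self):
        G = xd.simulate_genotypes(np.array([0.999]), 2000, 10, X_NONPAR, seed=0)
        assert G.dosages[G.is_male].mean() > 0.99

    def test_domain_of_dosages(self):
        p = xd.draw_allele_frequencies(20, (0.05, 0.5), seed=2)
        G = xd.simulate_genotypes(p, 500, 500, X_NONPAR, seed=2)
        assert set(np.unique(G.dosages[G.is_male])) <= {0.0, 1.0}
        assert set(np.unique(G.dosages[G.is_female])) <= {0.0, 1.0, 2.0}
        G2 = G.recode(xd.MALE_02)
        assert set(np.unique(G2.dosages[G2.is_male])) <= {0.0, 2.0}

    def test_autosomes_diploid_in_both_sexes(self):
        p = np.full(5, 0.3)
        G = xd.simulate_genotypes(p, 400, 400, xd.AUTOSOME, seed=0)
        assert G.dosages[G.is_male].max() == 2.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            xd.simulate_genotypes(np.array([0.0, 0.5]), 10, 10, X_NONPAR, seed=0)

    def test_ld_blocks_induce_correlation(self):
        p = np.full(10, 0.5)
        G = xd.simulate_genotypes(p, 4000, 4000, X_NONPAR, seed=5,
                                  ld_blocks=[{"start": 0, "end": 5, "rho": 0.9}])
        females = G.dosages[G.is_female]
        r_in = np.corrcoef(females[:, 0], females[:, 1])[0, 1]
        r_out = np.corrcoef(females[:, 0], females[:, 7])[0, 1]
        assert r_in > 0.5 and abs(r_out) < 0.1


class TestDCStates:
    @pytest.mark.parametrize("pi,expect", [(0.0, 2.0), (1.0, 1.0)])
    def test_pure_states(self, pi, expect):
        assert np.all(xd.assign_dc_model(50, pi, seed=0) == expect)

    def test_rounding_rule_exact_count(self):
        d = xd.assign_dc_model(100, 0.15, seed=1)
        assert int((d == 1).sum()) == 15

    def test_explicit_d_values_validated(self):
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            xd.assign_dc_model(3, 0.0, d_values=[1.0, 2.5, 1.5], seed=0)
        d = xd.assign_dc_model(3, 0.0, d_values=[1.0, 1.5, 2.0], seed=0)
        assert np.array_equal(d, [1.0, 1.5, 2.0])


class TestEffects:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("d", [1.0, 1.5, 2.0])
    def test_variance_ratio_matches_enumeration(self, p, d):
        E = xd.draw_effects(np.array([p]), np.array([d]), 1, h2x_f=0.01, seed=0)
        got = E.genetic_variance(np.array([p]), "M") / E.genetic_variance(np.array([p]), "F")
        assert got == pytest.approx(enumerated_variance_ratio(p, d), rel=1e-12)

    def test_female_heritability_exact(self):
        p = xd.draw_allele_frequencies(100, (0.05, 0.5), seed=3)
        d = xd.assign_dc_model(40, 0.15, seed=3)
        E = xd.draw_effects(p, d, 40, h2x_f=0.01, seed=3)
        assert E.genetic_variance(p, "F") == pytest.approx(0.01, rel=1e-10)

    def test_escape_mixture_variance_ratio(self):
        # 85% d=2 / 15% d=1 with equal per-locus female variance: the
        # male/female variance ratio is 2*0.85 + 0.5*0.15 = 1.775 exactly
        p = xd.draw_allele_frequencies(100, (0.05, 0.5), seed=5)
        d = xd.assign_dc_model(100, 0.15, seed=5)
        E = xd.draw_effects(p, d, 100, h2x_f=0.01, equal_var_per_locus=True, seed=5)
        ratio = E.genetic_variance(p, "M") / E.genetic_variance(p, "F")
        assert ratio == pytest.approx(1.775, rel=1e-10)

    def test_single_locus_fdc_doubles_male_variance(self):
        E = xd.draw_effects(np.array([0.5]), np.array([2.0]), 1, h2x_f=0.01, seed=0)
        assert E.genetic_variance(np.array([0.5]), "M") == pytest.approx(0.02)

    def test_beta_m_invariant_with_delta(self):
        p = np.full(20, 0.3)
        E = xd.draw_effects(p, np.full(5, 2.0), 5, h2x_f=0.05, seed=1,
                            het_regions=[{"start": 10, "end": 15, "delta_sd": 0.3}])
        np.testing.assert_allclose(E.beta_m, E.d * E.beta_f + E.delta_m)
        assert np.any(E.delta_m[10:16] != 0)
        assert np.all(E.delta_m[:10] == 0)

    def test_zero_h2_with_causal_rejected(self):
        with pytest.raises(ValueError, match="h2x_f"):
            xd.draw_effects(np.full(5, 0.5), np.full(2, 2.0), 2, h2x_f=0.0, seed=0)


class TestPhenotypes:
    def test_standardised_copies(self, small_fdc_data):
        ph = small_fdc_data.phenotypes
        for label in ("M", "F"):
            mask = ph.sex == label
            assert ph.y_std[mask].mean() == pytest.approx(0.0, abs=1e-12)
            assert ph.y_std[mask].std() == pytest.approx(1.0, rel=1e-12)

    def test_overfull_heritability_rejected(self):
        p = np.array([0.5])
        G = xd.simulate_genotypes(p, 50, 50, X_NONPAR, seed=0)
        E = xd.draw_effects(p, np.array([2.0]), 1, h2x_f=0.45, seed=0)
        # male genetic variance is 2 * 0.45 = 0.9; background pushes past 1
        with pytest.raises(ValueError, match="residual variance"):
            xd.simulate_phenotypes(G, E, h2_bg=0.2, seed=0)

    def test_null_phenotype_gives_uniform_p(self, null_stats):
        from scipy import stats as sps
        sm, sf = null_stats
        assert sps.kstest(sm.table["p"], "uniform").pvalue > 0.01
        assert sps.kstest(sf.table["p"], "uniform").pvalue > 0.01

    def test_female_r2_matches_target_h2(self):
        # Monte-Carlo: summed causal-locus R^2 in females ~ h2x_f
        r2 = []
        for seed in range(3):
            cfg = xd.SimConfig(n_m=100, n_f=20_000, m_x=100, m_causal=10,
                               h2x_f=0.05, seed=seed)
            d = xd.simulate_dataset(cfg)
            fem = d.genotypes.is_female
            X = d.genotypes.dosages[fem][:, d.effects.causal_idx]
            y = d.phenotypes.y_std[fem]
            r = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])])
            r2.append((r**2).sum())
        assert np.mean(r2) == pytest.approx(0.05, abs=0.01)


class TestExpression:
    def test_d2_slope_recovery(self):
        p = xd.draw_allele_frequencies(10, (0.2, 0.5), seed=0)
        G = xd.simulate_genotypes(p, 20_000, 20_000, X_NONPAR, seed=0)
        expr = xd.simulate_expression(
            G, {"locus": 3, "variance_explained": 0.3, "d": 2.0}, seed=1)
        x = G.dosages[:, 3]
        m, f = G.is_male, G.is_female
        slope_m = np.polyfit(x[m], expr[m], 1)[0]
        slope_f = np.polyfit(x[f], expr[f], 1)[0]
        assert slope_m / slope_f == pytest.approx(2.0, abs=0.1)

    def test_max_variance_explained_female_r2(self):
        p = np.array([0.5])
        G = xd.simulate_genotypes(p, 100, 30_000, X_NONPAR, seed=2)
        expr = xd.simulate_expression(
            G, {"locus": 0, "variance_explained": 0.65, "d": 2.0}, seed=2)
        f = G.is_female
        r2 = np.corrcoef(G.dosages[f, 0], expr[f])[0, 1] ** 2
        assert r2 == pytest.approx(0.65, abs=0.02)

    def test_shift_without_eqtl(self):
        p = np.array([0.5])
        G = xd.simulate_genotypes(p, 1000, 1000, X_NONPAR, seed=3)
        expr = xd.simulate_expression(
            G, {"locus": 0, "variance_explained": 0.0, "mean_sex_diff": 0.5}, seed=3)
        res = xd.sex_diff_expression(expr, G.sex)
        assert res["p"] < 1e-6
        assert res["estimate"] == pytest.approx(0.5, abs=0.15)

    def test_non_x_locus_rejected(self):
        G = xd.simulate_genotypes(np.array([0.5]), 50, 50, xd.AUTOSOME, seed=0)
        with pytest.raises(ValueError, match="non-PAR"):
            xd.simulate_expression(G, {"locus": 0, "variance_explained": 0.1}, seed=0)


class TestDeterminism:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_dataset_reproducible_under_seed(self, seed):
        cfg = xd.SimConfig(n_m=50, n_f=50, m_x=20, m_causal=5, h2x_f=0.05)
        a = xd.simulate_dataset(cfg, seed=seed)
        b = xd.simulate_dataset(cfg, seed=seed)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert np.array_equal(a.phenotypes.y, b.phenotypes.y)

    def test_different_seeds_differ(self):
        cfg = xd.SimConfig(n_m=50, n_f=50, m_x=20, m_causal=5, h2x_f=0.05)
        a = xd.simulate_dataset(cfg, seed=1)
        b = xd.simulate_dataset(cfg, seed=2)
        assert not np.array_equal(a.genotypes.dosages, b.genotypes.dosages)


class TestIO:
    def test_vcf_round_trip(self, tmp_path):
        p = xd.draw_allele_frequencies(15, (0.1, 0.5), seed=0)
        G = xd.simulate_genotypes(p, 30, 40, X_NONPAR, seed=0)
        path = tmp_path / "g.vcf"
        xd.write_vcf(G, path)
        back = xd.read_vcf(path, G.sex)
        np.testing.assert_array_equal(back.dosages, G.dosages)
        assert list(back.variants["id"]) == list(G.variants["id"])

    def test_triplet_round_trip(self, tmp_path):
        p = xd.draw_allele_frequencies(10, (0.1, 0.5), seed=1)
        G = xd.simulate_genotypes(p, 20, 20, X_NONPAR, seed=1)
        xd.write_triplet(G, tmp_path / "trip")
        back = xd.read_triplet(tmp_path / "trip")
        np.testing.assert_array_equal(back.dosages, G.dosages)
        assert list(back.sex) == list(G.sex)

    def test_config_round_trip(self, tmp_path):
        cfg = xd.SimConfig(n_m=10, n_f=10, m_x=5, m_causal=2, h2x_f=0.05,
                           pi_escape=0.3, seed=7)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert xd.SimConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_config_validation(self):
        with pytest.raises(ValueError, match="pi_escape"):
            xd.SimConfig(pi_escape=1.5)
        with pytest.raises(ValueError, match="m_causal"):
            xd.SimConfig(m_x=10, m_causal=20)
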