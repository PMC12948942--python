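"""Synthetic-cohort generator: Mendelian transmission, effect covariance,
phenotype variance identities, item rendering, and PGS attenuation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from triofx.params import VCParams
from triofx import simulate as sim


class TestTrioGenotypes:
    def test_homozygote_parents_force_transmission(self, mo_cohort):
        geno, _, _ = mo_cohort
        both2 = (geno.mother_dosages == 2) & (geno.father_dosages == 2)
        assert np.all(geno.offspring_dosages[both2] == 2)
        both0 = (geno.mother_dosages == 0) & (geno.father_dosages == 0)
        assert np.all(geno.offspring_dosages[both0] == 0)

    def test_het_by_null_parent_transmission_is_fair_coin(self):
        # mother dosage 1, father 0 -> offspring 0 or 1 each w.p. 1/2
        config = sim.SimConfig(n_families=2000, n_snps=40, sibling_fraction=0.0, seed=3)
        geno = sim.simulate_trio_genotypes(config)
        cells = (geno.mother_dosages == 1) & (geno.father_dosages == 0)
        off = geno.offspring_dosages[cells]
        assert off.size > 10_000
        assert set(np.unique(off)) <= {0, 1}
        k = int((off == 1).sum())
        # 4-sigma binomial band around 1/2
        se = 0.5 * np.sqrt(off.size)
        assert abs(k - off.size / 2) < 4 * se

    def test_empirical_allele_freq_matches_generating_maf(self):
        config = sim.SimConfig(n_families=100, n_snps=1000, sibling_fraction=0.0, seed=5)
        geno = sim.simulate_trio_genotypes(config)
        parents = np.vstack([geno.mother_dosages, geno.father_dosages])
        emp = parents.mean(axis=0) / 2.0
        p = geno.allele_freqs
        se = np.sqrt(p * (1 - p) / (2 * parents.shape[0]))
        assert np.all(np.abs(emp - p) < 4 * se)

    def test_mendelian_consistency_everywhere(self, mo_cohort):
        geno, _, _ = mo_cohort
        assert sim.mendelian_consistent(geno).all()

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 40),
        m=st.integers(1, 30),
        frac=st.floats(0.0, 0.9),
        seed=st.integers(0, 10_000),
    )
    def test_mendelian_consistency_property(self, n, m, frac, seed):
        config = sim.SimConfig(n_families=n, n_snps=m, sibling_fraction=frac, seed=seed)
        geno = sim.simulate_trio_genotypes(config)
        assert sim.mendelian_consistent(geno).all()

    def test_sibling_clusters_share_mother_genotype(self, mo_config, mo_cohort):
        geno, _, _ = mo_cohort
        clusters = pd.Series(range(geno.n_families)).groupby(geno.maternal_cluster_ids).groups
        n_shared = 0
        for _, idx in clusters.items():
            idx = list(idx)
            for j in idx[1:]:
                assert np.array_equal(geno.mother_dosages[idx[0]], geno.mother_dosages[j])
                n_shared += 1
        assert n_shared == round(mo_config.sibling_fraction * mo_config.n_families)

    def test_bit_reproducible_given_seed(self, mo_config):
        a = sim.simulate_trio_genotypes(mo_config)
        b = sim.simulate_trio_genotypes(mo_config)
        assert np.array_equal(a.offspring_dosages, b.offspring_dosages)
        assert np.array_equal(a.allele_freqs, b.allele_freqs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.4, 0.2)},
            {"n_families": 0},
            {"n_snps": 0},
            {"pgs_r2": {"depression": 0.0}},
            {"missing_item_rate": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(sim.ConfigError):
            sim.SimConfig(**kwargs)


class TestEffectVectors:
    def test_zero_block_gives_zero_effects(self):
        config = sim.SimConfig(n_snps=50, truth=VCParams(sigma2_e=1.0), seed=1)
        effects = sim.draw_effect_vectors(config)
        assert np.all(effects.beta == 0.0)

    def test_diagonal_block_variance_concentration(self):
        truth = VCParams(sigma2_o=0.10, sigma2_m=0.10, sigma2_e=0.8)
        config = sim.SimConfig(n_snps=5000, truth=truth, seed=2)
        effects = sim.draw_effect_vectors(config)
        var_o = effects.beta[:, 0].var() * config.n_snps
        assert abs(var_o - 0.10) < 0.01
        assert np.all(effects.beta[:, 2] == 0.0)

    def test_negative_direct_maternal_correlation(self):
        # correlation -0.13 between direct and maternal-indirect effects
        s2o, s2m = 0.088, 0.104
        truth = VCParams(
            sigma2_o=s2o, sigma2_m=s2m, sigma_om=-0.13 * np.sqrt(s2o * s2m), sigma2_e=0.8
        )
        config = sim.SimConfig(n_snps=5000, truth=truth, seed=4)
        effects = sim.draw_effect_vectors(config)
        r = np.corrcoef(effects.beta[:, 0], effects.beta[:, 1])[0, 1]
        assert abs(r - (-0.13)) < 0.05


class TestLatentPhenotypes:
    def test_pure_noise_under_null_truth(self):
        config = sim.SimConfig(
            n_families=5000, n_snps=100, truth=VCParams(sigma2_e=1.0),
            fixed_effects={}, n_timepoints=1, sibling_fraction=0.0, seed=6,
        )
        geno = sim.simulate_trio_genotypes(config)
        effects = sim.draw_effect_vectors(config)
        pheno = sim.simulate_latent_phenotypes(geno, effects, config)
        assert abs(pheno["latent"].var() - 1.0) < 0.05

    def test_variance_identity_mo_truth(self):
        truth = VCParams(sigma2_o=0.088, sigma2_m=0.104, sigma_om=-0.012, sigma2_e=0.82)
        config = sim.SimConfig(
            n_families=5000, n_snps=800, truth=truth, fixed_effects={},
            n_timepoints=1, sibling_fraction=0.0, seed=8,
        )
        geno = sim.simulate_trio_genotypes(config)
        effects = sim.draw_effect_vectors(config)
        pheno = sim.simulate_latent_phenotypes(geno, effects, config)
        # E[z_child z_mother] = 1/2 under random mating, so the cross term
        # contributes 2 * (1/2) * sigma_om = sigma_om
        expected = 0.088 + 0.104 + (-0.012) + 0.82
        assert abs(pheno["latent"].var() / expected - 1) < 0.05

    def test_mother_father_covariance_moves_no_variance(self):
        base = dict(sigma2_o=0.0, sigma2_m=0.10, sigma2_p=0.10, sigma2_e=0.8)
        common = dict(
            n_families=4000, n_snps=500, fixed_effects={}, n_timepoints=1,
            sibling_fraction=0.0, seed=9,
        )
        out = {}
        for smp in (0.0, 0.05):
            config = sim.SimConfig(truth=VCParams(**base, sigma_mp=smp), **common)
            geno = sim.simulate_trio_genotypes(config)
            effects = sim.draw_effect_vectors(config)
            out[smp] = sim.simulate_latent_phenotypes(geno, effects, config)["latent"].var()
        assert abs(out[0.05] / out[0.0] - 1) < 0.05

    def test_shape_mismatch_rejected(self, mo_config, mo_cohort):
        geno, _, _ = mo_cohort
        bad = sim.EffectVectors(beta=np.zeros((mo_config.n_snps + 1, 3)))
        with pytest.raises(ValueError, match="SNPs"):
            sim.simulate_latent_phenotypes(geno, bad, mo_config)


class TestItemResponses:
    def _frame(self, latent):
        return pd.DataFrame(
            {"person_id": [f"p{i}" for i in range(len(latent))], "latent": latent}
        )

    def test_floor_category_for_very_low_latent(self):
        config = sim.SimConfig(missing_item_rate=0.0, missing_wave_rate=0.0,
                               item_noise_sd=0.0, seed=1)
        out = sim.render_item_responses(self._frame(np.full(10, -10.0)), config)
        assert (out[[f"item{j}" for j in range(1, 6)]] == 1).all().all()

    def test_marginals_match_normal_cdf_oracle(self):
        cut = (0.8, 1.6, 2.4)
        config = sim.SimConfig(
            item_cutpoints=cut, item_noise_sd=0.0,
            missing_item_rate=0.0, missing_wave_rate=0.0, seed=11,
        )
        latent = np.random.default_rng(0).standard_normal(20_000)
        out = sim.render_item_responses(self._frame(latent), config)
        probs = np.diff([0.0] + [sps.norm.cdf(c) for c in cut] + [1.0])
        # categories 1..4 occur with Phi-increment probabilities
        for j in range(1, 6):
            freq = out[f"item{j}"].value_counts(normalize=True).sort_index().to_numpy()
            assert np.all(np.abs(freq - probs) < 0.02)

    def test_no_masking_means_complete_items(self):
        config = sim.SimConfig(missing_item_rate=0.0, missing_wave_rate=0.0, seed=2)
        latent = np.random.default_rng(1).standard_normal(500)
        out = sim.render_item_responses(self._frame(latent), config)
        assert out[[f"item{j}" for j in range(1, 6)]].notna().all().all()

    def test_masking_rates_apply(self):
        config = sim.SimConfig(missing_item_rate=0.1, missing_wave_rate=0.2, seed=3)
        latent = np.zeros(20_000)
        out = sim.render_item_responses(self._frame(latent), config)
        missing = out[[f"item{j}" for j in range(1, 6)]].isna().to_numpy().mean()
        assert abs(missing - (0.2 + 0.8 * 0.1)) < 0.02


@pytest.fixture(scope="module")
def pgs_cohort():
    config = sim.SimConfig(
        n_families=2000, n_snps=2000, sibling_fraction=0.0,
        pgs_r2={"depression": 0.25, "ADHD": 1.0}, seed=13,
    )
    geno = sim.simulate_trio_genotypes(config)
    effects = sim.draw_effect_vectors(config)
    return sim.simulate_pgs(geno, effects, config)


class TestPGS:
    def test_perfect_proxy_is_rank_identical_to_true_value(self, pgs_cohort):
        sub = pgs_cohort[pgs_cohort["trait"] == "ADHD"]
        r = sps.spearmanr(sub["score"], sub["true_score"]).statistic
        assert r > 0.9999

    def test_attenuation_matches_target_r2(self, pgs_cohort):
        sub = pgs_cohort[pgs_cohort["trait"] == "depression"]
        r2 = np.corrcoef(sub["score"], sub["true_score"])[0, 1] ** 2
        assert abs(r2 - 0.25) < 0.05

    def test_parent_offspring_score_correlation_is_half(self, pgs_cohort):
        sub = pgs_cohort[pgs_cohort["trait"] == "ADHD"]
        wide = sub.pivot(index="family_id", columns="role", values="score")
        r = np.corrcoef(wide["mother"], wide["offspring"])[0, 1]
        assert abs(r - 0.5) < 0.05

    def test_scores_standardized(self, pgs_cohort):
        for _, sub in pgs_cohort.groupby("trait"):
            assert abs(sub["score"].mean()) < 1e-9
            assert abs(sub["score"].std(ddof=0) - 1) < 1e-9
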