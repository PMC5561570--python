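"""Generator contracts: HWE marginals, LD structure, cohort schema,
methylation linearity and determinism."""

import numpy as np
import pandas as pd
import pytest

from oracles import ols_beta

from mqtlsmoke.config import ConfigError, SimulationConfig
from mqtlsmoke.simulate import (
    simulate_cell_reference,
    simulate_cohort,
    simulate_genotypes,
    simulate_methylation,
    simulate_snp_map,
    simulate_study,
)


def _cfg(**kw):
    base = dict(
        n_discovery=50, n_validation=50, n_cpgs=4, snps_per_cpg=4,
        n_reference_cpgs=20, seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_cpgs": 0},
            {"maf_range": (0.0, 0.3)},
            {"maf_range": (0.3, 0.6)},
            {"smoking_prevalence": (0.5, 0.5, 0.5)},
            {"ld_rho": 1.0},
            {"dirichlet_alpha": (1.0, -1.0, 1.0, 1.0, 1.0, 1.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            _cfg(**kw)

    def test_roundtrip_through_dict(self):
        cfg = _cfg(maf_range=(0.1, 0.4))
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestGenotypes:
    def test_same_seed_is_bit_identical(self):
        cfg = _cfg()
        g1, m1 = simulate_genotypes(cfg, 200)
        g2, m2 = simulate_genotypes(cfg, 200)
        pd.testing.assert_frame_equal(g1.dosages, g2.dosages)
        pd.testing.assert_series_equal(m1, m2)

    def test_hwe_proportions_at_half_maf(self):
        cfg = _cfg(maf_range=(0.5, 0.5), missing_rate=0.0, n_cpgs=1,
                   snps_per_cpg=2)
        g, _ = simulate_genotypes(cfg, 100_000)
        col = g.dosages.iloc[:, 0]
        freqs = col.value_counts(normalize=True)
        assert abs(freqs[0.0] - 0.25) < 0.01
        assert abs(freqs[1.0] - 0.50) < 0.01
        assert abs(freqs[2.0] - 0.25) < 0.01

    def test_zero_ld_rho_gives_uncorrelated_loci(self):
        cfg = _cfg(ld_rho=0.0, missing_rate=0.0, n_cpgs=2, snps_per_cpg=6)
        g, _ = simulate_genotypes(cfg, 5000)
        X = g.dosages.to_numpy()
        rs = []
        for a in range(X.shape[1]):
            for b in range(a + 1, X.shape[1]):
                rs.append(np.corrcoef(X[:, a], X[:, b])[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_positive_ld_rho_correlates_within_blocks(self):
        cfg = _cfg(ld_rho=0.8, missing_rate=0.0, n_cpgs=2, snps_per_cpg=6,
                   ld_block_size=3)
        g, _ = simulate_genotypes(cfg, 5000)
        _, snp_map = simulate_snp_map(cfg)
        region = snp_map[snp_map["region_cpg"] == "cg000001"].index
        # adjacent loci inside a block approach the copy probability
        r_adj = np.corrcoef(
            g.dosages[region[0]], g.dosages[region[1]]
        )[0, 1]
        assert 0.6 < r_adj < 0.95

    def test_allele_frequencies_converge_to_truth(self):
        cfg = _cfg(missing_rate=0.0)
        n = 5000
        g, true_maf = simulate_genotypes(cfg, n)
        emp = g.dosages.mean(axis=0) / 2.0
        emp = np.minimum(emp, 1 - emp)
        se = np.sqrt(true_maf * (1 - true_maf) / (2 * n))
        assert (np.abs(emp - true_maf) < 3 * se + 1e-12).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            simulate_genotypes(_cfg(), 1)


class TestCohort:
    def test_degenerate_prevalence_all_current(self):
        cfg = _cfg(smoking_prevalence=(1.0, 0.0, 0.0))
        cohort = simulate_cohort(cfg, 200)
        assert (cohort["smoking_status"] == "current").all()
        assert (cohort["pack_years"] > 0).all()

    def test_prevalence_proportions_recovered(self):
        cfg = _cfg(smoking_prevalence=(0.18, 0.30, 0.52))
        cohort = simulate_cohort(cfg, 10_000)
        obs = cohort["smoking_status"].value_counts(normalize=True)
        assert abs(obs["current"] - 0.18) < 0.02
        assert abs(obs["former"] - 0.30) < 0.02
        assert abs(obs["never"] - 0.52) < 0.02

    def test_cessation_only_for_former(self):
        cohort = simulate_cohort(_cfg(), 500)
        has = cohort["cessation_time"].notna()
        assert (cohort.loc[has, "smoking_status"] == "former").all()
        assert (cohort.loc[cohort["smoking_status"] == "former",
                           "cessation_time"].notna()).all()

    def test_cell_proportions_sum_to_one(self):
        cohort = simulate_cohort(_cfg(), 100)
        cols = [c for c in cohort.columns if c.startswith("cell_prop_")]
        np.testing.assert_allclose(cohort[cols].sum(axis=1), 1.0, atol=1e-12)

    def test_followup_bounded_by_horizon(self):
        cfg = _cfg(followup_horizon=12.4)
        cohort = simulate_cohort(cfg, 500)
        assert (cohort["followup_time"] <= 12.4).all()
        assert (cohort["followup_time"] > 0).all()
        # censored subjects sit exactly at the administrative horizon
        assert (cohort.loc[cohort["dead"] == 0, "followup_time"] == 12.4).all()


class TestMethylation:
    def test_noiseless_constant_up_to_cell_mixture(self, rng):
        cfg = _cfg(noise_sd=0.0, batch_sd=0.0, n_batches=1, mqtl_fraction=0.0,
                   smoking_effect_range=(0.0, 0.0), missing_rate=0.0)
        cohort = simulate_cohort(cfg, 80)
        geno, maf = simulate_genotypes(cfg, 80, sample_ids=list(cohort["sample_id"]))
        manifest, _ = simulate_snp_map(cfg)
        meth, truth = simulate_methylation(
            cohort, geno, cfg, manifest=manifest, true_maf=maf
        )
        prop_cols = [c for c in cohort.columns if c.startswith("cell_prop_")]
        P = cohort[prop_cols].to_numpy()
        expected = P @ truth.cell_profiles.to_numpy().T
        np.testing.assert_allclose(meth.betas.to_numpy(), expected, atol=1e-12)

    def test_additive_mqtl_effect_is_exact_without_noise(self):
        cfg = _cfg(noise_sd=0.0, batch_sd=0.0, n_batches=1, mqtl_fraction=1.0,
                   mqtl_effect_range=(0.05, 0.05), missing_rate=0.0,
                   smoking_effect_range=(0.0, 0.0), maf_range=(0.4, 0.5))
        cohort = simulate_cohort(cfg, 400)
        geno, maf = simulate_genotypes(cfg, 400, sample_ids=list(cohort["sample_id"]))
        manifest, _ = simulate_snp_map(cfg)
        meth, truth = simulate_methylation(
            cohort, geno, cfg, manifest=manifest, true_maf=maf
        )
        prop_cols = [c for c in cohort.columns if c.startswith("cell_prop_")]
        mixture = pd.DataFrame(
            cohort[prop_cols].to_numpy() @ truth.cell_profiles.to_numpy().T,
            index=meth.betas.index, columns=meth.betas.columns,
        )
        signal = meth.betas - mixture  # leaves a_j * G exactly
        for cpg, snp in truth.causal_snp.items():
            g = geno.dosages[snp]
            mean2 = signal.loc[g == 2, cpg].mean()
            mean0 = signal.loc[g == 0, cpg].mean()
            assert abs(abs(mean2 - mean0) - 0.10) < 1e-9

    def test_noiseless_ols_recovers_generative_coefficients(self):
        cfg = _cfg(noise_sd=0.0, batch_sd=0.0, n_batches=1, mqtl_fraction=1.0,
                   missing_rate=0.0)
        cohort = simulate_cohort(cfg, 300)
        geno, maf = simulate_genotypes(cfg, 300, sample_ids=list(cohort["sample_id"]))
        manifest, _ = simulate_snp_map(cfg)
        meth, truth = simulate_methylation(
            cohort, geno, cfg, manifest=manifest, true_maf=maf
        )
        smoke = cohort["smoking_status"].map(
            {"never": 0.0, "former": 0.5, "current": 1.0}
        ).to_numpy()
        prop_cols = [c for c in cohort.columns if c.startswith("cell_prop_")]
        P = cohort[prop_cols].to_numpy()
        for cpg, snp in truth.causal_snp.items():
            y = meth.betas[cpg].to_numpy()
            if y.min() <= 0.0 or y.max() >= 1.0:
                continue  # clipped CpGs are not linear
            X = np.column_stack([geno.dosages[snp].to_numpy(), smoke, P])
            beta = ols_beta(y, X)
            assert abs(beta[0] - truth.mqtl_effect[cpg]) < 1e-8
            assert abs(beta[1] - truth.smoking_effect[cpg]) < 1e-8

    def test_misaligned_sample_ids_raise(self):
        cfg = _cfg()
        cohort = simulate_cohort(cfg, 50)
        geno, _ = simulate_genotypes(cfg, 50)  # default S-prefixed ids
        with pytest.raises(Exception, match="align"):
            simulate_methylation(cohort, geno, cfg)


class TestCellReference:
    def test_range_rank_and_determinism(self):
        cfg = _cfg(n_cell_types=2, dirichlet_alpha=(2.0, 3.0))
        ref1 = simulate_cell_reference(cfg)
        ref2 = simulate_cell_reference(cfg)
        vals = ref1.profiles.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert np.linalg.matrix_rank(vals) == 2
        pd.testing.assert_frame_equal(ref1.profiles, ref2.profiles)

    def test_full_rank_for_default_k(self):
        ref = simulate_cell_reference(_cfg())
        assert np.linalg.matrix_rank(ref.profiles.to_numpy()) == 6


class TestStudy:
    def test_clipping_fraction_below_one_percent(self):
        study = simulate_study(SimulationConfig(
            n_discovery=200, n_validation=150, n_cpgs=30, snps_per_cpg=6,
            n_reference_cpgs=40, seed=11,
        ))
        b = study.methylation.betas.to_numpy()
        clipped = ((b == 0.0) | (b == 1.0)).mean()
        assert clipped < 0.01

    def test_panels_share_truth_but_not_samples(self, small_study):
        cohort = small_study.cohort
        d = set(cohort.loc[cohort["panel"] == "discovery", "sample_id"])
        v = set(cohort.loc[cohort["panel"] == "validation", "sample_id"])
        assert not d & v
        assert small_study.genotypes.dosages.shape[0] == len(d) + len(v)

    def test_study_is_reproducible(self, small_config, small_study):
        again = simulate_study(small_config)
        pd.testing.assert_frame_equal(
            again.methylation.betas, small_study.methylation.betas
        )
        pd.testing.assert_frame_equal(again.cohort, small_study.cohort)
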