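import numpy as np
import pandas as pd
import pytest

from ewaspipe import marginal, seqfilters, synthetic
from ewaspipe.synthetic import SimulationConfig


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(spike_fraction=0.5)

    def test_h2_bounds(self):
        with pytest.raises(ValueError, match="target_h2"):
            SimulationConfig(target_h2=1.0)
        with pytest.raises(ValueError, match="target_h2"):
            SimulationConfig(target_h2=-0.1)

    def test_sizes(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_causal=2000, n_cpgs=100)


class TestMethylationCohort:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_individuals=50, n_cpgs=60, seed=1)
        m1, p1, t1 = synthetic.simulate_methylation_cohort(cfg)
        m2, p2, t2 = synthetic.simulate_methylation_cohort(cfg)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        m1.to_csv(a, sep="\t")
        m2.to_csv(b, sep="\t")
        assert a.read_bytes() == b.read_bytes()
        pd.testing.assert_frame_equal(p1, p2)
        assert np.array_equal(t1.effects, t2.effects)

    def test_beta_values_bounded(self, small_cohort):
        methylation, _, _ = small_cohort
        vals = methylation.to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_bookkeeping_exact(self, small_cohort):
        methylation, phenotypes, truth = small_cohort
        recomputed = np.var(truth.score) / np.var(phenotypes["trait"].to_numpy())
        assert truth.realized_h2 == pytest.approx(recomputed, abs=0, rel=0)

    def test_spike_label_iff_zero_effect(self, small_cohort):
        _, _, truth = small_cohort
        assert np.array_equal(truth.components == 0, truth.effects == 0.0)

    def test_null_h2_lambda_near_one(self):
        # empirical null: with no methylation signal the marginal EWAS is calibrated
        lams = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_individuals=150, n_cpgs=1000, target_h2=0.0, seed=seed,
                covariate_effects={},
            )
            m, ph, truth = synthetic.simulate_methylation_cohort(cfg)
            assert truth.realized_h2 == 0.0
            res = marginal.ewas_lm(m, ph["trait"].to_numpy())
            lams.append(marginal.genomic_inflation(res["p"]))
        assert abs(np.mean(lams) - 1.0) < 0.08

    def test_realized_h2_near_target_large_n(self):
        cfg = SimulationConfig(n_individuals=2000, n_cpgs=500, target_h2=0.5,
                               seed=3, covariate_effects={})
        _, _, truth = synthetic.simulate_methylation_cohort(cfg)
        assert 0.45 <= truth.realized_h2 <= 0.55

    def test_n_causal_pins_support(self):
        cfg = SimulationConfig(n_individuals=50, n_cpgs=200, n_causal=7, seed=2)
        _, _, truth = synthetic.simulate_methylation_cohort(cfg)
        assert (truth.components > 0).sum() == 7

    def test_ar1_correlation_knob(self):
        cfg = SimulationConfig(n_individuals=800, n_cpgs=50, seed=5,
                               target_h2=0.0, ar1_rho=0.7)
        m, _, _ = synthetic.simulate_methylation_cohort(cfg)
        vals = m.to_numpy()
        adjacent = [np.corrcoef(vals[:, j], vals[:, j + 1])[0, 1] for j in range(20)]
        assert np.mean(adjacent) > 0.4


class TestSmokingPhenotype:
    def test_never_fraction_one_all_zero(self):
        table = synthetic.simulate_smoking_phenotype(200, 1.0, seed=1)
        assert (table["pack_years"] == 0).all()
        assert (table["smoking_status"] == "never").all()

    def test_zero_corruption_flags_nothing(self):
        from ewaspipe.phenotype import flag_inconsistent_records

        table = synthetic.simulate_smoking_phenotype(400, 0.5, seed=2,
                                                     corruption_rate=0.0)
        mask, _ = flag_inconsistent_records(table)
        assert mask.sum() == 0

    def test_corruption_rate_binomial(self):
        from ewaspipe.phenotype import flag_inconsistent_records

        table = synthetic.simulate_smoking_phenotype(1000, 0.5, seed=3,
                                                     corruption_rate=0.1)
        mask, _ = flag_inconsistent_records(table)
        # binomial expectation 100, 3 SD ~ 28.5
        assert abs(int(mask.sum()) - 100) <= 29

    def test_category_consistency(self, questionnaire):
        t = questionnaire
        never = t["smoking_status"] == "never"
        assert (t.loc[never, "pack_years"] == 0).all()
        assert t.loc[never, "age_started"].isna().all()
        current = t["smoking_status"] == "current"
        assert t.loc[current, "age_stopped"].isna().all()
        assert (t.loc[current, "age_started"] < t.loc[current, "current_age"]).all()
        former = t["smoking_status"] == "former"
        assert (t.loc[former, "age_stopped"] > t.loc[former, "age_started"]).all()
        assert (t.loc[former, "age_stopped"] <= t.loc[former, "current_age"]).all()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_smoking_phenotype(10, 1.5, seed=0)


class TestCoverage:
    def test_low_depth_fails_retention(self):
        table, _ = synthetic.simulate_coverage(46, 200, "short_read_panel",
                                               mean_depth=0.5, seed=4)
        policy = seqfilters.FilterPolicy(min_samples=40, min_reads_platform=10)
        filtered, audit = seqfilters.apply_filters(table, policy)
        assert filtered.n_sites == 0
        assert audit["sites_removed"].sum() == 200

    def test_counts_are_valid(self):
        table, _ = synthetic.simulate_coverage(10, 50, "long_read",
                                               mean_depth=8.0, seed=5)
        assert (table.total >= 0).all()
        assert (table.meth <= table.total).all()

    def test_effect_site_power(self):
        hits = 0
        for seed in range(5):
            table, truth = synthetic.simulate_coverage(
                46, 50, "short_read_panel", mean_depth=30.0, seed=seed,
                n_effect_sites=1, effect_shift=0.3,
            )
            fractions = seqfilters.methylation_fraction(table)
            res = marginal.ewas_lm(fractions, truth.score)
            j = int(np.flatnonzero(truth.effects != 0)[0])
            if res["p"].iloc[j] < 1e-5:
                hits += 1
        assert hits >= 3  # designated shift detectable in the majority of seeds

    def test_null_has_no_genome_wide_hits(self):
        table, truth = synthetic.simulate_coverage(46, 300, "short_read_panel",
                                                   mean_depth=25.0, seed=6)
        fractions = seqfilters.methylation_fraction(table)
        res = marginal.ewas_lm(fractions, truth.score)
        assert (res["p"].dropna() < 3.6e-8).sum() <= 1

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            synthetic.simulate_coverage(5, 5, "short_read_panel", 0.0, seed=0)
        with pytest.raises(ValueError):
            synthetic.simulate_coverage(5, 5, "array", 5.0, seed=0)


class TestGenotypes:
    def test_fixed_maf_half(self):
        geno, _, _ = synthetic.simulate_genotypes(2000, 50, (0.5, 0.5), 0.0, 0, seed=1)
        af = geno.to_numpy().mean(axis=0) / 2.0
        assert np.abs(af - 0.5).max() < 0.05

    def test_dosage_domain(self):
        geno, _, _ = synthetic.simulate_genotypes(100, 100, (0.05, 0.5), 0.2, 10, seed=2)
        assert set(np.unique(geno.to_numpy())) <= {0, 1, 2}

    def test_null_lambda(self):
        from ewaspipe import gwas

        lams = []
        for seed in range(3):
            geno, ph, _ = synthetic.simulate_genotypes(400, 2000, (0.05, 0.5),
                                                       0.0, 0, seed=seed)
            res = gwas.gwas_scan(geno, ph["trait"])
            lams.append(res.attrs["lambda"])
        assert abs(np.mean(lams) - 1.0) < 0.1

    def test_single_causal_tops_scan(self):
        from ewaspipe import gwas

        wins = 0
        for seed in range(5):
            geno, ph, truth = synthetic.simulate_genotypes(
                2000, 200, (0.1, 0.5), 0.2, 1, seed=seed
            )
            res = gwas.gwas_scan(geno, ph["trait"])
            causal = int(np.flatnonzero(truth.effects != 0)[0])
            if res["p"].idxmin() == causal:
                wins += 1
        assert wins >= 3

    def test_errors(self):
        with pytest.raises(ValueError):
            synthetic.simulate_genotypes(10, 5, (0.05, 0.5), 0.2, 10, seed=0)
        with pytest.raises(ValueError):
            synthetic.simulate_genotypes(10, 5, (0.0, 0.5), 0.2, 1, seed=0)
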