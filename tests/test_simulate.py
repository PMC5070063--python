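"""Synthetic-data generator: determinism, planting, expression coupling."""

import numpy as np
import pytest

from tfactivity import (
    SimulationConfig,
    generate_promoter_set,
    group_fold_difference,
    plant_motif_instances,
    simulate_dataset,
    simulate_expression,
    simulate_null_dataset,
)
from tfactivity.simulate import (
    CovariateSpec,
    GroundTruth,
    SimulationError,
    expected_prevalence_ratio,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gc_content": 1.2},
            {"gc_content": -0.1},
            {"n_per_group": 1},
            {"noise_sd": 0.0},
            {"promoter_length": 0},
            {"planted_tf_effects": {"M": (1.5, 0.3)}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            SimulationConfig(**kwargs)

    def test_span_follows_length(self):
        assert SimulationConfig(promoter_length=1200).span == (-1000, 200)
        assert SimulationConfig(promoter_length=500).span == (-300, 200)


class TestPromoterGeneration:
    def test_counts_and_lengths(self):
        cfg = SimulationConfig(n_genes=10, promoter_length=1200, seed=1)
        ps = generate_promoter_set(cfg)
        assert len(ps) == 10
        assert all(len(s) == 1200 for s in ps.sequences.values())

    def test_pure_gc(self):
        cfg = SimulationConfig(n_genes=3, promoter_length=300, gc_content=1.0,
                               seed=1)
        ps = generate_promoter_set(cfg)
        assert all(set(s) <= {"G", "C"} for s in ps.sequences.values())

    def test_gc_fraction_within_binomial_bounds(self):
        cfg = SimulationConfig(n_genes=2, promoter_length=10_000,
                               gc_content=0.4, seed=2)
        seq = next(iter(generate_promoter_set(cfg).sequences.values()))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        sd = np.sqrt(0.4 * 0.6 / 10_000)
        assert abs(gc - 0.4) < 3 * sd

    def test_seed_determinism_and_stream_independence(self):
        a = generate_promoter_set(SimulationConfig(n_genes=5, seed=3))
        b = generate_promoter_set(SimulationConfig(n_genes=5, seed=3))
        assert a.sequences == b.sequences
        # enlarging the panel must not perturb existing genes
        c = generate_promoter_set(SimulationConfig(n_genes=8, seed=3))
        for gene, seq in a.sequences.items():
            assert c.sequences[gene] == seq


class TestPlanting:
    def test_zero_prevalence_is_identity(self, matrix_library):
        cfg = SimulationConfig(n_genes=5, seed=4)
        ps = generate_promoter_set(cfg)
        planted, counts = plant_motif_instances(
            ps, matrix_library[0], ps.gene_ids, prevalence=0.0, seed=1
        )
        assert planted.sequences == ps.sequences
        assert set(counts.values()) == {0}

    def test_full_prevalence_plants_everywhere(self, matrix_library):
        cfg = SimulationConfig(n_genes=10, seed=5)
        ps = generate_promoter_set(cfg)
        _, counts = plant_motif_instances(
            ps, matrix_library[0], ps.gene_ids, prevalence=1.0, seed=1
        )
        assert all(c >= 1 for c in counts.values())

    def test_binomial_planting_rate(self, matrix_library):
        cfg = SimulationConfig(n_genes=200, seed=6)
        ps = generate_promoter_set(cfg)
        _, counts = plant_motif_instances(
            ps, matrix_library[0], ps.gene_ids, prevalence=0.5, seed=2
        )
        planted = sum(counts.values())
        assert abs(planted - 100) < 3 * np.sqrt(200 * 0.25)

    def test_length_conserved_and_edits_bounded(self, matrix_library):
        pwm = matrix_library[2]
        cfg = SimulationConfig(n_genes=30, seed=7)
        ps = generate_promoter_set(cfg)
        planted, counts = plant_motif_instances(ps, pwm, ps.gene_ids, 0.5, seed=3)
        for gene in ps.gene_ids:
            before, after = ps.sequences[gene], planted.sequences[gene]
            assert len(before) == len(after)
            edits = sum(a != b for a, b in zip(before, after))
            assert edits <= counts[gene] * len(pwm)

    def test_unknown_gene_named(self, matrix_library):
        cfg = SimulationConfig(n_genes=3, seed=8)
        ps = generate_promoter_set(cfg)
        with pytest.raises(SimulationError, match="GHOST"):
            plant_motif_instances(ps, matrix_library[0], ["GHOST"], 0.5, seed=1)

    def test_motif_longer_than_promoter_rejected(self, matrix_library):
        cfg = SimulationConfig(n_genes=2, promoter_length=5, seed=9)
        ps = generate_promoter_set(cfg)
        with pytest.raises(SimulationError, match="exceeds"):
            plant_motif_instances(ps, matrix_library[2], ps.gene_ids, 1.0, seed=1)


class TestExpression:
    def test_noise_free_limit_recovers_effect(self):
        cfg = SimulationConfig(n_genes=4, n_per_group=5, noise_sd=1e-9,
                               expression_effect=0.5, seed=10)
        truth = GroundTruth(
            true_effect={g: 0.5 if g in cfg.up_destined() else -0.5
                         for g in cfg.gene_ids()}
        )
        m = simulate_expression(cfg, truth)
        folds = group_fold_difference(m, "case", "control")
        for g in cfg.up_destined():
            assert folds[g] == pytest.approx(2 ** 0.5, rel=1e-6)

    def test_null_effect_false_positive_rate(self):
        """With zero effects the >15% screen fires at the rate implied by the
        noise model (Monte-Carlo oracle: |mean diff| > log2(1.15) with
        sd = noise*sqrt(2/n))."""
        from scipy import stats

        cfg = SimulationConfig(n_genes=2000, n_per_group=20, noise_sd=0.3,
                               expression_effect=0.0, seed=11)
        truth = GroundTruth(true_effect={g: 0.0 for g in cfg.gene_ids()})
        m = simulate_expression(cfg, truth)
        folds = group_fold_difference(m, "case", "control")
        hit = ((folds > 1.15) | (folds < 1 / 1.15)).mean()
        se = 0.3 * np.sqrt(2 / 20)
        expected = 2 * stats.norm.sf(np.log2(1.15) / se)
        assert abs(hit - expected) < 3 * np.sqrt(expected * (1 - expected) / 2000)

    def test_covariates_shift_expression(self):
        spec = CovariateSpec("age", mean=45.0, sd=10.0, slope=0.05)
        cfg = SimulationConfig(n_genes=3, n_per_group=10, noise_sd=1e-9,
                               covariate_spec=[spec], seed=12)
        truth = GroundTruth(true_effect={g: 0.0 for g in cfg.gene_ids()})
        m = simulate_expression(cfg, truth)
        assert m.covariates is not None and "age" in m.covariates
        gene = cfg.gene_ids()[0]
        centered = m.values.loc[gene] - m.values.loc[gene].mean()
        predicted = 0.05 * (m.covariates["age"] - m.covariates["age"].mean())
        np.testing.assert_allclose(centered, predicted, atol=1e-6)

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=6, seed=13)
        truth = GroundTruth(true_effect={g: 0.1 for g in cfg.gene_ids()})
        a = simulate_expression(cfg, truth)
        b = simulate_expression(cfg, truth)
        assert a.values.equals(b.values)


class TestDatasets:
    def test_null_dataset_has_unit_expected_ratios(self):
        cfg = SimulationConfig(n_genes=20, seed=14)
        *_, truth = simulate_null_dataset(cfg)
        assert all(r == 1.0 for r in truth.expected_ratio.values())

    def test_null_rejects_unequal_prevalence(self):
        cfg = SimulationConfig(
            n_genes=20, seed=15,
            planted_tf_effects={"SYN_CREB_LIKE": (0.5, 0.2)},
        )
        with pytest.raises(SimulationError, match="equal"):
            simulate_null_dataset(cfg)

    def test_expected_ratio_arithmetic(self):
        assert expected_prevalence_ratio(0.6, 0.3, 100, 100) == pytest.approx(2.0)
        assert expected_prevalence_ratio(0.0, 0.0, 10, 10) == pytest.approx(1.0)

    def test_full_dataset_determinism(self):
        cfg = SimulationConfig(n_genes=20, seed=16)
        p1, e1, _, t1 = simulate_null_dataset(cfg)
        p2, e2, _, t2 = simulate_null_dataset(cfg)
        assert p1.sequences == p2.sequences
        assert e1.values.equals(e2.values)
        assert t1.planted_counts == t2.planted_counts

    def test_coupled_dataset_prevalence_differs_between_sets(self):
        cfg = SimulationConfig(
            n_genes=400, seed=17,
            planted_tf_effects={"SYN_ISRE_LIKE": (0.6, 0.3)},
        )
        *_, truth = simulate_dataset(cfg)
        counts = truth.planted_counts["SYN_ISRE_LIKE"]
        up_rate = np.mean([counts[g] for g in truth.up_genes])
        down_rate = np.mean([counts[g] for g in truth.down_genes])
        assert abs(up_rate - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 200)
        assert abs(down_rate - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 200)
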