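"""Synthetic dataset generator: placement, determinism, count model,
noiseless mark structure."""

import numpy as np
import pandas as pd
import pytest

from endosign.config import SimulationConfig
from endosign.errors import ConfigurationError, InputError
from endosign.synthetic_data import (
    generate_annotation,
    generate_truth,
    simulate_counts,
    simulate_dataset,
    simulate_marks,
)


def biallelic_config(**kwargs):
    defaults = dict(
        class_fractions={"biallelic": 1.0},
        n_genes=200,
        chrom_length=2_000_000,
        seed=3,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_class_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(class_fractions={"PEG": 0.5, "biallelic": 0.4})

    def test_biallelic_fraction_must_be_two_thirds(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                maternal_fraction_by_class={"PEG": 0.1, "MEG": 0.95, "biallelic": 0.5}
            )

    def test_contamination_bounds(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(contamination=1.5)

    def test_mark_effect_missing_class_rejected(self):
        cfg = SimulationConfig(n_genes=20, chrom_length=200_000)
        cfg.mark_effect = {"MEG": cfg.mark_effect["MEG"], "biallelic": cfg.mark_effect["biallelic"]}
        genes = generate_annotation(cfg)
        with pytest.raises(ConfigurationError, match="PEG"):
            generate_truth(genes, cfg)


class TestAnnotation:
    def test_single_gene_within_chromosome(self):
        cfg = SimulationConfig(n_genes=1, chrom_length=10_000, seed=0)
        (gene,) = generate_annotation(cfg)
        assert 0 <= gene.start < gene.end <= 10_000

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_genes=50, chrom_length=500_000, seed=5)
        a = generate_annotation(cfg)
        b = generate_annotation(SimulationConfig(n_genes=50, chrom_length=500_000, seed=5))
        assert a == b

    def test_lengths_in_range_and_no_overlap(self):
        cfg = SimulationConfig(
            n_genes=200, chrom_length=2_000_000, gene_length_range=(1000, 3000), seed=9
        )
        genes = generate_annotation(cfg)
        assert len(genes) == 200
        for g in genes:
            assert 1000 <= g.length <= 3000
        ordered = sorted(genes, key=lambda g: g.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start
        assert ordered[-1].end <= cfg.chrom_length

    def test_infeasible_placement_names_constraint(self):
        with pytest.raises(ConfigurationError, match="chromosome"):
            generate_annotation(SimulationConfig(n_genes=100, chrom_length=50_000))


class TestTruth:
    def test_every_gene_exactly_once(self, small_config):
        genes = generate_annotation(small_config)
        truth = generate_truth(genes, small_config)
        assert sorted(truth["gene_id"]) == sorted(g.gene_id for g in genes)
        assert not truth["gene_id"].duplicated().any()

    def test_class_counts_match_fractions(self, small_config):
        genes = generate_annotation(small_config)
        truth = generate_truth(genes, small_config)
        counts = truth["imprinting_class"].value_counts()
        assert counts["PEG"] == 6 and counts["MEG"] == 6 and counts["biallelic"] == 48


class TestCounts:
    def test_full_contamination_all_maternal(self):
        cfg = biallelic_config(contamination=1.0, n_genes=50, chrom_length=500_000)
        genes = generate_annotation(cfg)
        truth = generate_truth(genes, cfg)
        counts = simulate_counts(genes, truth, cfg)
        assert (counts["paternal"] == 0).all()
        assert counts["maternal"].sum() > 0

    def test_pooled_biallelic_fraction_matches_mixture_mean(self):
        cfg = biallelic_config(
            contamination=0.15, n_genes=2000, chrom_length=12_000_000, sequencing_depth=100
        )
        genes = generate_annotation(cfg)
        truth = generate_truth(genes, cfg)
        counts = simulate_counts(genes, truth, cfg)
        f = counts["maternal"].sum() / (counts["maternal"] + counts["paternal"]).sum()
        assert f == pytest.approx((1 - 0.15) * (2 / 3) + 0.15, abs=0.01)

    def test_reciprocal_directions_and_replicates_present(self, small_config):
        genes = generate_annotation(small_config)
        truth = generate_truth(genes, small_config)
        counts = simulate_counts(genes, truth, small_config)
        assert set(counts["direction"]) == {"ColxLer", "LerxCol"}
        assert set(counts["replicate"]) == {1, 2}
        per_gene = counts.groupby("gene_id").size()
        assert (per_gene == 4).all()

    def test_deterministic_for_fixed_seed(self, small_config):
        genes = generate_annotation(small_config)
        truth = generate_truth(genes, small_config)
        a = simulate_counts(genes, truth, small_config)
        b = simulate_counts(genes, truth, small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_truth_mismatch_rejected(self, small_config):
        genes = generate_annotation(small_config)
        truth = generate_truth(genes, small_config).iloc[:-1]
        with pytest.raises(InputError):
            simulate_counts(genes, truth, small_config)


class TestMarks:
    def test_noiseless_maternal_peg_signal_is_baseline_plus_effect(self):
        cfg = SimulationConfig(n_genes=30, chrom_length=300_000, noise_sd=0.0, seed=2)
        genes = generate_annotation(cfg)
        truth = generate_truth(genes, cfg)
        marks = simulate_marks(genes, truth, cfg)
        cls = dict(zip(truth["gene_id"], truth["imprinting_class"]))
        chrom = cfg.chrom_name
        step = cfg.track_step
        chip = marks.chip[("H3K27me3", "maternal")].values[chrom]
        h3 = marks.h3["maternal"].values[chrom]
        log2r = np.log2(chip / h3)
        for g in genes:
            body = slice(g.start // step, -(-g.end // step))
            expected = 2.0 if cls[g.gene_id] == "PEG" else 0.0
            np.testing.assert_allclose(log2r[body], expected, atol=1e-9)

    def test_null_effect_leaves_classes_identical_in_expectation(self):
        cfg = SimulationConfig(n_genes=40, chrom_length=400_000, seed=4)
        cfg.mark_effect = {c: {f: 0.0 for f in cfg.mark_effect[c]} for c in cfg.mark_effect}
        genes = generate_annotation(cfg)
        truth = generate_truth(genes, cfg)
        assert (truth["mu_H3K27me3_maternal"] == 0).all()
        assert truth["p_CHG_central_cell"].nunique() == 1

    def test_h3_control_positive_everywhere(self, small_config):
        genes = generate_annotation(small_config)
        truth = generate_truth(genes, small_config)
        marks = simulate_marks(genes, truth, small_config)
        for allele in ("maternal", "paternal"):
            assert (marks.h3[allele].values[small_config.chrom_name] > 0).all()

    def test_methylation_counts_consistent(self, small_config):
        genes = generate_annotation(small_config)
        truth = generate_truth(genes, small_config)
        marks = simulate_marks(genes, truth, small_config)
        for source, recs in marks.methylation.items():
            assert (recs["count_methylated"] >= 0).all()
            assert (recs["count_unmethylated"] >= 0).all()
            assert set(recs["context"]) == {"CG", "CHG", "CHH"}

    def test_central_cell_chg_elevated_on_pegs(self, small_config):
        ds = simulate_dataset(small_config)
        from endosign.methylation import methylation_levels_nonoverlapping

        levels = methylation_levels_nonoverlapping(
            ds.marks.methylation["central_cell"], ds.genes, "CHG"
        )
        cls = dict(zip(ds.truth["gene_id"], ds.truth["imprinting_class"]))
        peg = [levels[g] for g in levels.index if cls[g] == "PEG"]
        bi = [levels[g] for g in levels.index if cls[g] == "biallelic"]
        assert np.nanmean(peg) > np.nanmean(bi) + 0.2
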