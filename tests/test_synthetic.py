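"""Synthetic-study generator: determinism, planted structure, count moments."""

import numpy as np
import pytest

from medipseq.reads import KmerIndex, Read, align_exact, deduplicate_clonal, trim_reads
from medipseq.simulate import (SimulationConfig, simulate_counts,
                               simulate_expression, simulate_genome,
                               simulate_reads, simulate_study,
                               simulate_window_truth, write_study)
from medipseq.expression import expression_bias


class TestDeterminism:
    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_genes=20, n_chromosomes=2,
                               reads_per_sample=500)
        p1 = write_study(simulate_study(cfg), tmp_path / "a")
        p2 = write_study(simulate_study(cfg), tmp_path / "b")
        for key in p1:
            with open(p1[key], "rb") as f1, open(p2[key], "rb") as f2:
                assert f1.read() == f2.read(), key

    def test_different_seeds_differ(self, tmp_path):
        g1, _ = simulate_genome(SimulationConfig(seed=1, n_chromosomes=1,
                                                 n_genes=5))
        g2, _ = simulate_genome(SimulationConfig(seed=2, n_chromosomes=1,
                                                 n_genes=5))
        assert g1.sequences["chr1"] != g2.sequences["chr1"]


class TestGenome:
    def test_gene_free_genome(self):
        ann, _ = simulate_genome(SimulationConfig(seed=0, n_genes=0))
        assert ann.genes == []

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome(SimulationConfig(seed=0, n_genes=100_000))

    def test_repeat_family_multimaps_by_construction(self):
        """32-mers from a planted multi-copy family align to every copy."""
        from medipseq.simulate import RepeatFamily

        cfg = SimulationConfig(
            seed=4, n_genes=0, n_chromosomes=2,
            repeat_families=(RepeatFamily("fam", 4, 300),),
            centromere_satellite_copies=0,
        )
        ann, _ = simulate_genome(cfg)
        fam = [r for r in ann.repeats if r.class_label == "fam"]
        assert len(fam) == 4
        index = KmerIndex(ann.sequences)
        probe = ann.sequences[fam[0].chrom][fam[0].start + 50:fam[0].start + 82]
        records, _ = align_exact([Read("p", probe)], index)
        assert records[0].n_placements == 4

    def test_centromere_region_is_repeat_dense(self):
        cfg = SimulationConfig(seed=5)
        ann, _ = simulate_genome(cfg)
        mid = cfg.chrom_length // 2
        sat = [r for r in ann.repeats if r.class_label == "centromeric-satellite"]
        assert sat
        assert all(abs((r.start + r.end) / 2 - mid)
                   <= cfg.centromere_halfwidth for r in sat)


class TestTruth:
    def test_window_truth_fractions_match_config(self):
        cfg = SimulationConfig(seed=6)
        truth = simulate_window_truth(cfg, 50_000)
        any_t = truth.any(axis=1)
        all_t = truth.all(axis=1)
        assert all_t.mean() == pytest.approx(cfg.frac_ubiquitous, abs=0.005)
        expected_any = cfg.frac_ubiquitous + 7 * cfg.frac_tissue_specific
        assert any_t.mean() == pytest.approx(expected_any, abs=0.01)


class TestCounts:
    def test_null_study_is_exchangeable_with_input(self):
        cfg = SimulationConfig(seed=6, enrichment_fold=1.0)
        truth = simulate_window_truth(cfg, 5_000)
        sim = simulate_counts(cfg, truth)
        medip = sim.counts[sim.samples[~sim.samples.is_input].index]
        inputs = sim.counts[sim.samples[sim.samples.is_input].index]
        assert medip.to_numpy().mean() == pytest.approx(
            inputs.to_numpy().mean(), rel=0.03)

    def test_poisson_flag_gives_variance_near_mean(self):
        cfg = SimulationConfig(seed=6, nb_dispersion=None, enrichment_fold=1.0)
        truth = simulate_window_truth(cfg, 20_000)
        sim = simulate_counts(cfg, truth)
        col = sim.counts.iloc[:, 0].to_numpy()
        assert col.var() == pytest.approx(col.mean(), rel=0.05)

    def test_enriched_windows_hit_fold_times_mean(self):
        """fold=8, input mean 20 -> methylated-window sample mean ~160."""
        cfg = SimulationConfig(seed=6)
        truth = simulate_window_truth(cfg, 20_000)
        sim = simulate_counts(cfg, truth)
        meth = truth["leaf"].to_numpy()
        leaf = sim.counts[[s for s in sim.counts
                           if s.startswith("leaf")]].to_numpy().mean(axis=1)
        assert leaf[meth].mean() == pytest.approx(160, rel=0.05)
        assert leaf[~meth].mean() == pytest.approx(20, rel=0.05)


class TestReads:
    def test_clonal_rate_round_trips_through_dedup(self, small_sim_config,
                                                   small_study):
        reads = simulate_reads(small_sim_config, small_study.annotation,
                               small_study.grid, small_study.truth.window)
        sample = [Read(i, s) for i, s in reads["leaf_rep1"]]
        trimmed, _ = trim_reads(sample)
        _, removed = deduplicate_clonal(trimmed)
        assert removed / len(sample) == pytest.approx(
            small_sim_config.clonal_rate, abs=0.05)

    def test_organelle_contamination_rate(self, small_sim_config, small_study):
        from medipseq.reads import filter_organelle, split_unique_multi

        reads = simulate_reads(small_sim_config, small_study.annotation,
                               small_study.grid, small_study.truth.window)
        sample = [Read(i, s) for i, s in reads["input_lane1"]]
        deduped, _ = deduplicate_clonal(sample)
        index = KmerIndex(small_study.annotation.sequences)
        records, _ = align_exact(deduped, index)
        kept, removed = filter_organelle(
            records, small_study.annotation.organelle_names)
        assert removed / len(records) == pytest.approx(
            small_sim_config.organelle_rate, abs=0.02)

    def test_zero_reads_gives_empty_samples(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genes=5, n_chromosomes=1,
                               reads_per_sample=0)
        study = simulate_study(cfg)
        reads = simulate_reads(cfg, study.annotation, study.grid,
                               study.truth.window)
        assert all(len(v) == 0 for v in reads.values())


class TestExpression:
    def test_planted_bias_genes_clear_threshold(self, small_study,
                                                small_sim_config):
        expr = simulate_expression(small_sim_config, small_study.truth)
        hits = 0
        total = 0
        for t, genes in small_study.truth.biased_genes.items():
            for g in genes:
                total += 1
                if expression_bias(expr.loc[g], [t]) >= 0.9:
                    hits += 1
        assert hits / total >= 0.9  # sampling noise at the boundary allowed

    def test_no_effect_flag_decouples_expression_from_methylation(self,
                                                                  small_study):
        from medipseq.expression import mann_whitney

        # per-tissue tests share gene baselines, so rejections are
        # correlated within one draw; average over independent draws
        n_significant = n_tests = 0
        for seed in (1, 2, 3):
            cfg = SimulationConfig(seed=seed, promoter_effect=1.0,
                                   body_effect=1.0, n_biased_per_tissue=0,
                                   bias_factor=1.0)
            expr = simulate_expression(cfg, small_study.truth)
            for t in cfg.tissues:
                body = small_study.truth.gene_body[t]
                res = mann_whitney(expr.loc[body[body].index, t],
                                   expr.loc[body[~body].index, t])
                n_significant += res.pvalue < 0.05
                n_tests += 1
        assert n_significant <= 0.1 * n_tests + 1

    def test_body_effect_depresses_body_only_genes(self, small_study,
                                                   small_sim_config):
        expr = simulate_expression(small_sim_config, small_study.truth)
        prom = small_study.truth.gene_promoter["leaf"]
        body = small_study.truth.gene_body["leaf"]
        body_only = expr.loc[(body & ~prom)[lambda s: s].index, "leaf"]
        unmeth = expr.loc[(~body & ~prom)[lambda s: s].index, "leaf"]
        assert body_only.median() < unmeth.median()
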