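"""Synthetic study generator: determinism, constraints, planted truth."""

import numpy as np
import pandas as pd
import pytest

from markgene.enrichment import gene_enrichment_table, metagene_profile
from markgene.expression import ExpressionTable, classify_de
from markgene.genome import (
    H3K27ME3,
    H3K4ME3,
    mark_region,
    read_alignments_bed,
    read_gene_annotation,
)
from markgene.simulate import (
    SimulationConfig,
    simulate_chip_library,
    simulate_expression,
    simulate_genes,
    simulate_input_library,
    simulate_study,
)


class TestSimulationConfig:
    def test_defaults_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"de_fraction": 1.5},
            {"background_fraction": -0.1},
            {"k4_sigma": 0.0},
            {"n_genes": 0},
            {"count_dispersion": 0.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateGenes:
    def test_nonoverlapping_with_disjoint_windows(self):
        cfg = SimulationConfig(n_genes=10, chrom_length=1_000_000, n_chroms=1)
        genes = simulate_genes(cfg)
        assert len(genes) == 10
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.locus.chrom, []).append(g)
        for chrom_genes in by_chrom.values():
            chrom_genes.sort(key=lambda g: g.locus.start)
            for a, b in zip(chrom_genes, chrom_genes[1:]):
                assert b.locus.start - a.locus.end >= cfg.gene_spacing
                # +/-2 kb promoter windows disjoint
                ra = mark_region(a, H3K4ME3)
                rb = mark_region(b, H3K4ME3)
                assert not ra.overlaps(rb)

    def test_deterministic(self):
        cfg = SimulationConfig(n_genes=25, seed=99)
        a = simulate_genes(cfg)
        b = simulate_genes(cfg)
        assert [(g.gene_id, g.locus, g.transcript_length) for g in a] == [
            (g.gene_id, g.locus, g.transcript_length) for g in b
        ]

    def test_genome_too_small(self):
        cfg = SimulationConfig(n_genes=100, chrom_length=100_000, n_chroms=1)
        with pytest.raises(ValueError, match="genome too small"):
            simulate_genes(cfg)

    def test_strand_proportions(self):
        cfg = SimulationConfig(
            n_genes=2_000, chrom_length=15_000_000, n_chroms=2, seed=4
        )
        genes = simulate_genes(cfg)
        n_plus = sum(g.locus.strand == "+" for g in genes)
        # binomial 99% CI around 0.5 for n = 2000
        half_width = 2.576 * np.sqrt(0.25 / 2_000)
        assert abs(n_plus / 2_000 - 0.5) <= half_width

    def test_lengths_within_range(self):
        cfg = SimulationConfig(n_genes=200, seed=8)
        for g in simulate_genes(cfg):
            assert cfg.gene_min_length <= g.transcript_length <= cfg.gene_max_length


class TestSimulateExpression:
    def test_null_effect_all_unchanged(self):
        cfg = SimulationConfig(n_genes=50, expr_log2fc_effect=0.0, seed=2)
        genes = simulate_genes(cfg)
        _, _, truth = simulate_expression(cfg, genes)
        assert (truth["de_class"] == "unchanged").all()
        assert (truth["expr_log2fc"] == 0).all()

    def test_deterministic_counts(self):
        cfg = SimulationConfig(n_genes=40, seed=3)
        genes = simulate_genes(cfg)
        c1, _, _ = simulate_expression(cfg, genes)
        c2, _, _ = simulate_expression(cfg, genes)
        pd.testing.assert_frame_equal(c1, c2)

    def test_half_up_half_down(self):
        cfg = SimulationConfig(n_genes=100, de_fraction=0.2, seed=5)
        genes = simulate_genes(cfg)
        _, _, truth = simulate_expression(cfg, genes)
        counts = truth["de_class"].value_counts()
        assert counts["up"] == 10 and counts["down"] == 10

    def test_recovery_at_threshold_three(self):
        # strong effect, low dispersion, deep counts, and a small DE
        # fraction (FPKM fold changes shrink toward 1 as planted genes
        # inflate the test genotype's library total)
        cfg = SimulationConfig(
            n_genes=400,
            chrom_length=16_000_000,
            expr_log2fc_effect=2.0,
            de_fraction=0.1,
            count_dispersion=5e-4,
            baseline_log2_mean=10.0,
            baseline_log2_sd=0.8,
            seed=6,
        )
        genes = simulate_genes(cfg)
        counts, sample_genotypes, truth = simulate_expression(cfg, genes)
        lengths = pd.Series(
            [float(g.transcript_length) for g in genes], index=counts.index
        )
        table = ExpressionTable(counts, lengths, sample_genotypes)
        fc = table.fold_changes(cfg.genotype_test, cfg.genotype_ref, threshold=3.0)
        planted = truth["de_class"] != "unchanged"
        recovered = (
            fc.de_class.loc[planted] == truth.loc[planted, "de_class"]
        ).mean()
        assert recovered >= 0.95

    def test_bad_de_fraction_too_few(self):
        cfg = SimulationConfig(n_genes=10, de_fraction=0.1, seed=1)
        genes = simulate_genes(cfg)
        with pytest.raises(ValueError):
            simulate_expression(cfg, genes)


class TestSimulateChipLibrary:
    def test_background_one_indistinguishable_from_input(self):
        cfg = SimulationConfig(
            n_genes=50,
            chrom_length=2_000_000,
            n_chroms=1,
            reads_per_chip_library=100_000,
            reads_per_input_library=100_000,
            background_fraction=1.0,
            seed=9,
        )
        genes = simulate_genes(cfg)
        chip, expected = simulate_chip_library(
            cfg, genes, H3K4ME3, "XY", np.full(50, 4.0),
            rng=np.random.default_rng(1),
        )
        inp = simulate_input_library(cfg, "XY", H3K4ME3, rng=np.random.default_rng(2))
        tab = gene_enrichment_table(genes, chip, inp, H3K4ME3, "XY")
        assert np.allclose(expected, 1.0)
        assert abs(tab["enrichment"].mean() - 1.0) < 0.1

    def test_library_total_matches_config(self, small_study):
        cfg = small_study.config
        for (mark, fraction, _), lib in small_study.libraries.items():
            expected = (
                cfg.reads_per_chip_library
                if fraction == "chip"
                else cfg.reads_per_input_library
            )
            assert lib.total_mapped == expected

    def test_reads_within_chromosome_bounds(self, small_study):
        cfg = small_study.config
        for lib in small_study.libraries.values():
            assert (lib.starts >= 0).all()
            assert (lib.ends <= cfg.chrom_length).all()

    def test_single_hot_gene_stands_out(self):
        # one gene at 8x over 99 unit-ratio genes
        cfg = SimulationConfig(
            n_genes=100,
            chrom_length=4_000_000,
            n_chroms=1,
            reads_per_chip_library=100_000,
            reads_per_input_library=100_000,
            seed=10,
        )
        genes = simulate_genes(cfg)
        ratios = np.ones(100)
        ratios[0] = 8.0
        chip, _ = simulate_chip_library(
            cfg, genes, H3K27ME3, "XY", ratios, rng=np.random.default_rng(3)
        )
        inp = simulate_input_library(cfg, "XY", H3K27ME3, rng=np.random.default_rng(4))
        tab = gene_enrichment_table(genes, chip, inp, H3K27ME3, "XY")
        hot = tab["enrichment"].iloc[0]
        median = tab["enrichment"].iloc[1:].median()
        assert 6.4 <= hot / median <= 9.6

    def test_k4_profile_peaks_at_tss(self, small_study):
        # bins of 200 bp: wide relative to the placement sigma, so the
        # argmax is stable at this depth
        prof = metagene_profile(
            small_study.libraries[(H3K4ME3, "chip", "XY")],
            small_study.genes,
            n_bins=20,
        )
        tss_bin = 10
        assert abs(int(np.argmax(prof.density)) - tss_bin) <= 1

    def test_ratio_validation(self, small_study):
        cfg = small_study.config
        with pytest.raises(ValueError):
            simulate_chip_library(
                cfg, small_study.genes, H3K4ME3, "XY",
                np.zeros(len(small_study.genes)),
            )


class TestSimulateStudy:
    def test_truth_covers_every_gene(self, small_study):
        assert set(small_study.truth.index) == {
            g.gene_id for g in small_study.genes
        }

    def test_coupling_direction(self, small_study):
        truth = small_study.truth
        down = truth["de_class"] == "down"
        up = truth["de_class"] == "up"
        cfg = small_study.config
        ref, test = cfg.genotype_ref, cfg.genotype_test
        assert (
            truth.loc[down, f"k4_ratio_{test}"]
            < truth.loc[down, f"k4_ratio_{ref}"]
        ).all()
        assert (
            truth.loc[down, f"k27_ratio_{test}"]
            > truth.loc[down, f"k27_ratio_{ref}"]
        ).all()
        assert (
            truth.loc[up, f"k4_ratio_{test}"] > truth.loc[up, f"k4_ratio_{ref}"]
        ).all()

    def test_null_coupling_centred_fold_changes(self):
        cfg = SimulationConfig(
            n_genes=200,
            chrom_length=3_000_000,
            n_chroms=2,
            reads_per_chip_library=100_000,
            reads_per_input_library=100_000,
            k4_coupling=0.0,
            k27_coupling=0.0,
            seed=13,
        )
        study = simulate_study(cfg)
        ref_tab = gene_enrichment_table(
            study.genes,
            study.libraries[(H3K4ME3, "chip", cfg.genotype_ref)],
            study.libraries[(H3K4ME3, "input", cfg.genotype_ref)],
            H3K4ME3,
            cfg.genotype_ref,
        )
        test_tab = gene_enrichment_table(
            study.genes,
            study.libraries[(H3K4ME3, "chip", cfg.genotype_test)],
            study.libraries[(H3K4ME3, "input", cfg.genotype_test)],
            H3K4ME3,
            cfg.genotype_test,
        )
        log2fc = np.log2(test_tab["enrichment"] / ref_tab["enrichment"])
        assert abs(log2fc.mean()) <= 0.05

    def test_stronger_coupling_lowers_down_class_p(self):
        """Mean down-class log p decreases monotonically in the K4
        coupling (reduced scale: 6 seeds per coupling)."""
        from markgene.integrate import mark_vs_expression_test

        mean_logp = []
        for coupling in (0.0, 0.5, 1.0, 2.0):
            logps = []
            for seed in range(6):
                cfg = SimulationConfig(
                    n_genes=80,
                    chrom_length=3_000_000,
                    n_chroms=1,
                    de_fraction=0.5,
                    reads_per_chip_library=20_000,
                    reads_per_input_library=20_000,
                    k4_coupling=coupling,
                    k27_coupling=0.0,
                    seed=1000 + seed,
                )
                study = simulate_study(cfg)
                tabs = {}
                for genotype in (cfg.genotype_ref, cfg.genotype_test):
                    tabs[genotype] = gene_enrichment_table(
                        study.genes,
                        study.libraries[(H3K4ME3, "chip", genotype)],
                        study.libraries[(H3K4ME3, "input", genotype)],
                        H3K4ME3,
                        genotype,
                    )["enrichment"]
                p = mark_vs_expression_test(
                    tabs[cfg.genotype_ref], tabs[cfg.genotype_test],
                    study.truth["de_class"],
                )["down"].p_value
                logps.append(np.log10(max(p, 1e-300)))
            mean_logp.append(np.mean(logps))
        assert all(b < a for a, b in zip(mean_logp, mean_logp[1:]))

    def test_written_study_roundtrips(self, small_config, tmp_path):
        study = simulate_study(small_config, outdir=tmp_path)
        genes = read_gene_annotation(tmp_path / "genes.bed12")
        assert [(g.gene_id, g.locus) for g in genes] == [
            (g.gene_id, g.locus) for g in study.genes
        ]
        gtf_genes = read_gene_annotation(tmp_path / "genes.gtf")
        assert [(g.gene_id, g.locus) for g in gtf_genes] == [
            (g.gene_id, g.locus) for g in study.genes
        ]
        for key, lib in study.libraries.items():
            mark, fraction, genotype = key
            back = read_alignments_bed(
                tmp_path / f"reads_{mark}_{fraction}_{genotype}.bed", unique_only=True
            )
            assert back.total_mapped == lib.total_mapped
            assert np.array_equal(back.starts, lib.starts)

    def test_byte_identical_outputs(self, small_config, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        simulate_study(small_config, outdir=out1)
        simulate_study(small_config, outdir=out2)
        for path1 in sorted(out1.iterdir()):
            path2 = out2 / path1.name
            if path1.name == "config.yaml":
                continue  # embeds absolute paths
            assert path1.read_bytes() == path2.read_bytes(), path1.name
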