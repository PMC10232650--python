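"""Synthetic-data generator: determinism, conservation and planted truth."""

import dataclasses
import io

import numpy as np
import pytest
from scipy.stats import binomtest

from circtrans.simulate import (
    ConfigurationError,
    SimConfig,
    apply_rnase_r,
    plant_circles,
    simulate_fractionation_counts,
    simulate_genome,
    simulate_junction_counts,
    simulate_reads,
    simulate_rnase_r_counts,
    write_fastq,
)


def test_forced_single_gene_structure():
    cfg = SimConfig(n_genes=1, exons_per_gene=(3, 3), exon_len=(100, 100), n_circles=1,
                    n_de=1, n_coding=1)
    _, genes = simulate_genome(cfg)
    assert len(genes) == 1
    assert genes[0].n_exons == 3
    assert genes[0].transcript_length == 300


def test_exon_lengths_within_configured_range_exhaustively():
    cfg = SimConfig(n_genes=20, exons_per_gene=(4, 12), exon_len=(100, 300), seed=3)
    _, genes = simulate_genome(cfg)
    for gene in genes:
        assert 4 <= gene.n_exons <= 12
        for ex in gene.exons:
            assert 100 <= ex.length <= 300
        # genomic intervals are non-overlapping and ordered
        ivs = sorted((e.start, e.end) for e in gene.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2


def test_degenerate_ranges_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(exon_len=(300, 100))
    with pytest.raises(ConfigurationError):
        SimConfig(error_rate=1.5)
    with pytest.raises(ConfigurationError):
        SimConfig(planted_fc=0.0)
    with pytest.raises(ConfigurationError):
        SimConfig(n_pairs=0)


def test_genome_determinism_is_byte_identical():
    cfg = SimConfig(seed=42)
    g1, genes1 = simulate_genome(cfg)
    g2, genes2 = simulate_genome(cfg)
    assert g1 == g2
    assert genes1 == genes2


def test_planted_circles_are_contiguous_runs_with_correct_lengths(small_dataset):
    _, genes, truth, _, _ = small_dataset
    gene_by_id = {g.gene_id: g for g in genes}
    for c in truth.circles:
        gene = gene_by_id[c.gene_id]
        assert 0 <= c.first_exon <= c.last_exon < gene.n_exons
        assert c.circle_len == sum(
            gene.exons[k].length for k in range(c.first_exon, c.last_exon + 1)
        )


def test_planted_set_cardinalities_and_size_prior():
    cfg = SimConfig(n_genes=20, n_circles=10, n_de=4, n_coding=3,
                    circle_len_max_frac_under_1000=1.0, seed=5)
    _, genes = simulate_genome(cfg)
    truth = plant_circles(genes, cfg)
    assert len(truth.circles) == 10
    assert len(truth.de_set) == 4
    assert len(truth.coding_set) == 3
    assert all(c.circle_len < 1000 for c in truth.circles)


def test_requesting_more_circles_than_runs_fails():
    cfg = SimConfig(n_genes=1, exons_per_gene=(2, 2), exon_len=(100, 120),
                    n_circles=10, n_de=1, n_coding=1)
    _, genes = simulate_genome(cfg)
    with pytest.raises(ConfigurationError):
        plant_circles(genes, cfg)


def test_read_conservation_against_truth_table(small_dataset, small_config):
    _, _, _, rna, ribo = small_dataset
    for readset in (rna, ribo):
        assert sum(len(v) for v in readset.reads.values()) == len(readset.truth)
        for sample in small_config.samples:
            assert len(readset.reads[sample]) == (readset.truth["sample"] == sample).sum()


def test_error_free_junction_read_matches_pseudo_sequence(small_dataset, planted_library):
    _, _, _, rna, _ = small_dataset
    _, entries = planted_library
    by_id = {e.circ_id: e for e in entries}
    t = rna.truth
    spanning = t[(t.spans_junction == 1) & (t.left_overlap >= 10) & (t.right_overlap >= 10)]
    row = spanning.iloc[0]
    entry = by_id[row.source_id]
    seqs = dict(rna.reads[row["sample"]])
    read = seqs[row.read_id]
    offset = entry.left_flank_len - row.left_overlap
    assert entry.pseudo_seq[offset : offset + len(read)] == read


def test_junction_spanning_fraction_matches_binomial_expectation():
    """For a circle of length L and read length r, the chance a circle read
    spans the junction is (r-1)/L."""
    cfg = SimConfig(n_genes=4, n_circles=1, n_de=0, n_coding=0, n_pairs=1,
                    exons_per_gene=(3, 3), exon_len=(150, 150),
                    n_rna_reads=50_000, n_ribo_reads=0, error_rate=0.0,
                    base_abundance=(2.0, 0.1), seed=9)
    genome, genes = simulate_genome(cfg)
    truth = plant_circles(genes, cfg)
    (circle,) = truth.circles
    _rna, _ = simulate_reads(genome, genes, truth, cfg)
    t = _rna.truth
    circ_reads = t[t.source_id == circle.circ_id]
    n_span = int(circ_reads.spans_junction.sum())
    p_expected = (cfg.rna_read_len - 1) / circle.circle_len
    res = binomtest(n_span, len(circ_reads), p_expected)
    assert res.pvalue > 0.001


def test_no_ribo_junction_reads_outside_coding_set():
    cfg = SimConfig(n_genes=8, n_circles=4, n_de=2, n_coding=0,
                    n_rna_reads=0, n_ribo_reads=5000, error_rate=0.0, seed=13)
    genome, genes = simulate_genome(cfg)
    truth = plant_circles(genes, cfg)
    _, ribo = simulate_reads(genome, genes, truth, cfg)
    assert truth.coding_set == set()
    assert int(ribo.truth.spans_junction.sum()) == 0


def test_read_determinism_and_seed_sensitivity(small_config, small_dataset):
    genome, genes, truth, rna, _ = small_dataset
    rna2, _ = simulate_reads(genome, genes, truth, small_config)
    assert rna.reads == rna2.reads
    cfg_b = dataclasses.replace(small_config, seed=small_config.seed + 1)
    genome_b, genes_b = simulate_genome(cfg_b)
    truth_b = plant_circles(genes_b, cfg_b)
    rna_b, _ = simulate_reads(genome_b, genes_b, truth_b, cfg_b)
    assert rna_b.reads != rna.reads


def test_fastq_format_and_quality(tmp_path, small_dataset):
    _, _, _, rna, _ = small_dataset
    sample = next(iter(rna.reads))
    path = tmp_path / "x.fastq"
    write_fastq(rna.reads[sample][:5], path)
    lines = path.read_text().splitlines()
    assert len(lines) == 20
    for i in range(0, 20, 4):
        assert lines[i].startswith("@")
        assert lines[i + 2] == "+"
        assert lines[i + 3] == "I" * len(lines[i + 1])


def test_apply_rnase_r_scales_by_survival():
    circ, lin = apply_rnase_r([100.0], [100.0], 0.9, 0.05)
    assert circ[0] == pytest.approx(90.0)
    assert lin[0] == pytest.approx(5.0)
    circ, lin = apply_rnase_r([3.0, 7.0], [2.0], 1.0, 1.0)
    assert list(circ) == [3.0, 7.0] and list(lin) == [2.0]
    with pytest.raises(ConfigurationError):
        apply_rnase_r([1.0], [1.0], 1.2, 0.5)
    with pytest.raises(ValueError):
        apply_rnase_r([-1.0], [1.0], 0.9, 0.05)


def test_assay_count_models_recover_configured_rates():
    cfg = SimConfig(seed=21)
    r = simulate_rnase_r_counts(cfg, depth=100_000)
    assert r["circ_treated"] / r["circ_untreated"] == pytest.approx(0.9, abs=0.01)
    assert r["linear_treated"] / r["linear_untreated"] == pytest.approx(0.05, abs=0.01)
    f = simulate_fractionation_counts(cfg, depth=100_000)
    assert f["cytoplasmic"] / (f["cytoplasmic"] + f["nuclear"]) == pytest.approx(
        0.75, abs=0.01
    )


def test_simulated_counts_scale_with_planted_fold_change():
    cfg = SimConfig(n_genes=25, n_circles=20, n_de=5, planted_fc=8.0, seed=2)
    _, genes = simulate_genome(cfg)
    truth = plant_circles(genes, cfg)
    cm = simulate_junction_counts(truth, cfg, mean_depth=200.0)
    tumor = cm.counts[[f"T{i+1}" for i in range(cfg.n_pairs)]].mean(axis=1)
    normal = cm.counts[[f"N{i+1}" for i in range(cfg.n_pairs)]].mean(axis=1)
    ratio = (tumor + 1) / (normal + 1)
    de = truth.de_set
    assert ratio[list(de)].min() > 4
    assert ratio[[c for c in ratio.index if c not in de]].max() < 2
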