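import pytest

from circtrans.backsplice import CircleCandidate, build_junction_library
from circtrans.simulate import SimConfig, plant_circles, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small paired design: 8 genes, 5 planted circles, error-free reads."""
    return SimConfig(
        n_genes=8,
        n_circles=5,
        n_de=2,
        n_coding=2,
        n_rna_reads=4000,
        n_ribo_reads=4000,
        error_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(genome, genes, truth, rna_reads, ribo_reads) for the small design."""
    genome, genes = simulate_genome(small_config)
    truth = plant_circles(genes, small_config)
    rna, ribo = simulate_reads(genome, genes, truth, small_config)
    return genome, genes, truth, rna, ribo


@pytest.fixture(scope="session")
def planted_library(small_dataset, small_config):
    """Junction library over the planted circles, flank = RNA read length
    (so every junction-straddling read fits in the pseudo-sequence)."""
    genome, genes, truth, _, _ = small_dataset
    gene_by_id = {g.gene_id: g for g in genes}
    candidates = [
        CircleCandidate(
            circ_id=c.circ_id,
            gene_id=c.gene_id,
            first_exon=c.first_exon,
            last_exon=c.last_exon,
            circle_len=c.circle_len,
            contig=gene_by_id[c.gene_id].contig,
            start=gene_by_id[c.gene_id].span[0],
            end=gene_by_id[c.gene_id].span[1],
            strand=gene_by_id[c.gene_id].strand,
        )
        for c in truth.circles
    ]
    entries = build_junction_library(
        candidates, genes, genome, flank=small_config.rna_read_len
    )
    return candidates, entries
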