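import pytest

from pathcons import SimulationSpec, simulate_genesets, simulate_genome, simulate_scan


@pytest.fixture(scope="session")
def small_spec():
    """A reduced study: 120 genes, short contigs, one planted 25-gene set."""
    return SimulationSpec(
        n_genes=120,
        gene_len=2000,
        gap_len=4000,
        genes_per_chrom=40,
        snps_per_gene=3.0,
        intergenic_snp_frac=0.3,
        theta=2.0,
        causal_sets=("SET0001",),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return simulate_genome(small_spec)


@pytest.fixture(scope="session")
def small_sets(small_genome, small_spec):
    return simulate_genesets(small_genome, n_sets=20, size_mean=25.0, seed=small_spec.seed)


@pytest.fixture(scope="session")
def small_scan(small_spec, small_genome, small_sets):
    return simulate_scan(small_spec, small_genome, small_sets)
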