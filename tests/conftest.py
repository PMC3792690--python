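import pytest

from chirpkit.io import GeneAnnotation, GeneModel, GenomicInterval
from chirpkit.simulate import SyntheticConfig


def make_gene(gene_id, chrom, start, end, strand="+", name=None):
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        strand=strand,
        gene_name=name,
    )


@pytest.fixture
def small_annotation():
    return GeneAnnotation(
        [
            make_gene("geneA", "chr1", 8_000, 20_000, "+"),
            make_gene("geneB", "chr1", 40_000, 50_000, "-"),
            make_gene("geneC", "chr2", 1_000, 5_000, "+"),
        ]
    )


@pytest.fixture
def fast_config():
    """Small synthetic config for quick end-to-end tests."""
    return SyntheticConfig(
        seed=11,
        chrom_lengths={"chr1": 3_000_000, "chr2": 3_000_000},
        n_genes=300,
        n_true_sites=60,
        n_noise_per_replicate=60,
        n_subthreshold_per_replicate=30,
        control_n_peaks=40,
    )
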