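import pytest

from polyrearrange import pipeline
from polyrearrange import synthetic_data as synth
from polyrearrange.formats_io import read_sam


@pytest.fixture(scope="session")
def genome():
    """Default synthetic allotetraploid (2 subgenomes x 3 chromosomes x 200
    genes; one reciprocal translocation, one inversion, one segmental
    duplication planted)."""
    return synth.simulate_genomes(synth.SimConfig(seed=1))


@pytest.fixture(scope="session")
def synteny_result(genome):
    return pipeline.analyze_synthetic(genome)


@pytest.fixture(scope="session")
def panel(genome, tmp_path_factory):
    """Simulated 20-accession panel (10 carriers / 10 non-carriers, 10x)."""
    bp = genome.truth.inversion_breakpoints
    outdir = tmp_path_factory.mktemp("panel")
    sams, genotypes = synth.simulate_panel_alignments(genome.config, bp, outdir)
    return sams, genotypes


@pytest.fixture(scope="session")
def pooled_noncarrier_pairs(panel):
    sams, genotypes = panel
    pooled = []
    for acc, path in sams.items():
        if genotypes[acc] == "absent":
            pooled.extend(read_sam(path, min_mapq=20))
    return pooled


def gene_tolerance(genome) -> int:
    """Endpoint tolerance of 'within one gene': the scale of one gene plus
    one intergenic gap in the simulated genome."""
    cfg = genome.config
    return 2 * cfg.chrom_length // cfg.genes_per_chrom
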