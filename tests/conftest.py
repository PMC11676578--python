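import numpy as np
import pytest

from popmut import (
    Locus,
    PopulationMap,
    SnpGenotypeMatrix,
    SnpSimParams,
    simulate_snp_dataset,
)

_BASES = "ACGT"


def make_matrix(genotypes, sample_ids=None, chrom="1", ref="A", alt="G"):
    """Build a SnpGenotypeMatrix from a (samples x loci) array of dosages."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_loci = genotypes.shape
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    loci = [Locus(chrom, 100 + 10 * j, ref, alt) for j in range(n_loci)]
    return SnpGenotypeMatrix(list(sample_ids), loci, genotypes)


@pytest.fixture(scope="session")
def neutral_sim():
    """A symmetric (exchangeable-population) simulated dataset with truth."""
    params = SnpSimParams(n_loci=5000, seed=11)
    matrix, popmap, truth = simulate_snp_dataset(params)
    return params, matrix, popmap, truth


@pytest.fixture
def tiny_popmap():
    return PopulationMap({"S0": "p1", "S1": "p1", "S2": "p2", "S3": "p2"})
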