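import numpy as np
import pandas as pd
import pytest

from malus.popgen import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ma1_fixture():
    """Genotype fixture reproducing the printed acidity-locus (Ma1-style)
    population counts: sylvestris 10 hom-ref + 1 het; sieversii 16/16/4;
    domestica 4/24/8."""
    from malus.simulate import simulate_genotype_matrix

    return simulate_genotype_matrix(
        {
            "sylvestris": (10, 1, 0),
            "sieversii": (16, 16, 4),
            "domestica": (4, 24, 8),
        }
    )


def make_matrix(genotypes, positions=None, populations=None, qual=None, chrom="chr1"):
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    return GenotypeMatrix(
        genotypes=g,
        samples=[f"s{i}" for i in range(n_samples)],
        populations=np.asarray(populations or ["pop"] * n_samples, dtype=object),
        chrom=np.asarray([chrom] * n_sites, dtype=object),
        positions=np.asarray(positions if positions is not None else np.arange(1, n_sites + 1)),
        qual=qual,
    )
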