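import numpy as np
import pytest

import heterosim as hs


@pytest.fixture(scope="session")
def small_map():
    """3 chromosomes x 80 loci, 20 QTL + 15 markers per chromosome."""
    gmap = hs.make_genome_map(n_chromosomes=3, n_loci_per_chr=80, rng_seed=101)
    return hs.sample_qtl_and_markers(gmap, n_qtl_per_chr=20, n_markers_per_chr=15, rng_seed=102)


@pytest.fixture(scope="session")
def founders(small_map):
    return hs.simulate_founder_haplotypes(60, 2, small_map, rng_seed=103)


@pytest.fixture(scope="session")
def arch(small_map, founders):
    """Scaled diploid architecture with directional dominance (meanDD = 1)."""
    raw = hs.sample_architecture(small_map, mean_dd=1.0, var_dd=0.2, ploidy=2, rng_seed=104)
    return hs.scale_architecture(raw, founders)


@pytest.fixture(scope="session")
def founders4(small_map):
    return hs.simulate_founder_haplotypes(40, 4, small_map, rng_seed=105)


@pytest.fixture(scope="session")
def arch4(small_map, founders4):
    raw = hs.sample_architecture(small_map, mean_dd=1.0, var_dd=0.2, ploidy=4, rng_seed=106)
    return hs.scale_architecture(raw, founders4)


def make_population(dosage_rows, ploidy=2, pool="single"):
    """Hand-built population from per-individual dosage vectors.

    Dosage x becomes x copies of the alternate allele on the first
    haplotypes (allele order within an individual is exchangeable).
    """
    dosage_rows = np.atleast_2d(np.asarray(dosage_rows))
    n, n_loci = dosage_rows.shape
    haps = np.zeros((n, ploidy, n_loci), dtype=np.uint8)
    for i in range(n):
        for j in range(n_loci):
            haps[i, : dosage_rows[i, j], j] = 1
    return hs.Population(
        haplotypes=haps,
        ids=np.arange(n, dtype=np.int64),
        pedigree=np.full((n, 2), -1, dtype=np.int64),
        pool=pool,
    )
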