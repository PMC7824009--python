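import numpy as np
import pytest

from tetrapanel import SimConfig
from tetrapanel import io as tio
from tetrapanel.simulate import simulate_dataset


@pytest.fixture(scope="session")
def study_sim():
    """Default-scale simulated study: 8 families x 11 offspring + 4
    ancestors (n=92), ~5,100 array SNPs over 12 pseudomolecules + 2
    unanchored groups."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def filtered_genotypes(study_sim):
    """The study genotypes after the standard filter chain."""
    g = tio.filter_missingness(study_sim.genotypes, 10)
    g = tio.filter_identity(g, study_sim.identity, 97.0)
    return tio.filter_maf(g, 0.05)


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast population for pipeline-level tests."""
    cfg = SimConfig(seed=5, offspring_per_family=6, loci_per_chrom=60,
                    loci_per_unanchored=10, n_qtl=8)
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-sized tetraploid matrix: 4 samples x 3 markers."""
    dos = np.array([
        [0.0, 2.0, 4.0],
        [1.0, np.nan, 3.0],
        [2.0, 2.0, 2.0],
        [4.0, 0.0, 0.0],
    ])
    return tio.DosageMatrix(["s1", "s2", "s3", "s4"], ["m1", "m2", "m3"], dos)


def random_dosage_matrix(rng, n_samples, n_markers, missing_rate=0.0,
                         ploidy=4):
    dos = rng.integers(0, ploidy + 1, size=(n_samples, n_markers)).astype(float)
    if missing_rate:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    # guard against all-missing markers
    for j in range(n_markers):
        if np.isnan(dos[:, j]).all():
            dos[0, j] = float(rng.integers(0, ploidy + 1))
    return tio.DosageMatrix(
        [f"s{i}" for i in range(n_samples)],
        [f"m{j}" for j in range(n_markers)], dos, ploidy=ploidy,
    )
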