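import numpy as np
import pytest

from hapblock.genotype_io import GenotypeMatrix
from hapblock.sim_pedigree import SimConfig, simulate_panel


def matrix_from_sites(sites, sample_ids=None):
    """Build a GenotypeMatrix from [(chrom, pos, allele-code sequence), ...]."""
    chroms = np.asarray([s[0] for s in sites], dtype=object)
    pos = np.asarray([s[1] for s in sites], dtype=np.int64)
    rows = np.asarray([[int(c) for c in s[2]] for s in sites], dtype=np.int8)
    n = rows.shape[1]
    m = GenotypeMatrix(
        chrom=chroms,
        pos=pos,
        ref=np.full(len(sites), "A", dtype=object),
        alt=np.full(len(sites), "T", dtype=object),
        alleles=rows,
        sample_ids=sample_ids or [f"s{i + 1:02d}" for i in range(n)],
    )
    m.validate()
    return m


@pytest.fixture(scope="session")
def small_config():
    """Two-chromosome panel with the default 20-line family + group design."""
    return SimConfig(n_chrom=2, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)
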