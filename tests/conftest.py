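import numpy as np
import pytest

from tandemdiv.io import GeneRecord
from tandemdiv.simulate import SimulationParams, simulate_family


def make_gene(
    gene_id,
    start,
    end=None,
    chromosome="chr1",
    family=False,
    exons=None,
    strand="+",
):
    end = end if end is not None else start + 999
    if exons is None:
        exons = ((start, end),)
    return GeneRecord(
        gene_id=gene_id,
        chromosome=chromosome,
        start=start,
        end=end,
        strand=strand,
        exons=exons,
        is_family_member=family,
    )


def random_gene_layout(rng, n_genes=100, n_chroms=2, family_fraction=0.3):
    """Random non-overlapping gene layout for detector property tests."""
    genes = []
    for chrom_idx in range(n_chroms):
        chrom = f"c{chrom_idx + 1}"
        pos = 1
        for _ in range(int(np.ceil(n_genes / n_chroms))):
            pos += int(rng.integers(100, 60_000))
            length = int(rng.integers(300, 8_000))
            genes.append(
                make_gene(
                    f"{chrom}_g{len(genes):04d}",
                    pos,
                    pos + length,
                    chromosome=chrom,
                    family=bool(rng.random() < family_fraction),
                )
            )
            pos += length
    return genes[:n_genes]


@pytest.fixture(scope="session")
def sim_family():
    """One simulated two-species family shared across tests (seed 1)."""
    return simulate_family(SimulationParams(rng_seed=1))


@pytest.fixture(scope="session")
def sim_paths(sim_family, tmp_path_factory):
    """The same family written out as files."""
    outdir = tmp_path_factory.mktemp("simdata")
    return sim_family.write(outdir)
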