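import numpy as np
import pandas as pd
import pytest

from fastz.core import AUTOSOME, GenotypeMatrix
from fastz.simulate import SimConfig, simulate_dataset


def build_matrix(genotypes, pops, sexes, chroms=None, pos=None, ref=None, alt=None,
                 chrom_class=None, contig_lengths=None, callable_intervals=None,
                 depth=None, gq=None):
    """Construct a small GenotypeMatrix from plain lists.

    ``genotypes``: (n_sites, n_samples, 2) array-like with 0/1 alleles,
    -1 missing, -2 absent (hemizygous second slot).
    """
    alleles = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = alleles.shape[:2]
    names = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame({"population": pops, "sex": sexes}, index=names)
    chroms = chroms if chroms is not None else ["chr1"] * n_sites
    sites = pd.DataFrame({
        "chrom": chroms,
        "pos": pos if pos is not None else np.arange(n_sites),
        "ref": ref if ref is not None else ["A"] * n_sites,
        "alt": alt if alt is not None else ["G"] * n_sites,
    })
    if chrom_class is None:
        chrom_class = {c: AUTOSOME for c in set(chroms)}
    if contig_lengths is None:
        contig_lengths = {c: int(max(sites.loc[sites.chrom == c, "pos"])) + 1
                          for c in set(chroms)}
    m = GenotypeMatrix(samples=samples, sites=sites, alleles=alleles,
                       chrom_class=chrom_class, contig_lengths=contig_lengths,
                       callable_intervals=callable_intervals or {},
                       depth=None if depth is None else np.asarray(depth, dtype=np.int32),
                       gq=None if gq is None else np.asarray(gq, dtype=np.int32))
    return m


@pytest.fixture
def make_matrix():
    return build_matrix


@pytest.fixture(scope="session")
def sim_bundle():
    """One modest no-migration dataset shared across tests."""
    cfg = SimConfig(n_autosomal_loci=60, n_z_loci=60, samples_per_pop=4,
                    seed=20260930)
    matrix, truth = simulate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def sim_bundle_migration():
    """Dataset with strong recent P3 -> P2 gene flow."""
    cfg = SimConfig(n_autosomal_loci=150, n_z_loci=60, samples_per_pop=4,
                    seed=20260931, migration_rate=2e-5)
    matrix, truth = simulate_dataset(cfg)
    return cfg, matrix, truth
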