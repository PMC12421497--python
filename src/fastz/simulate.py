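"""ZW-aware multi-population coalescent data generator.

Emulates the structure of the empirical data the pipeline targets: two sister
species pairs ((P1, P2), (P3, P4)) plus an outgroup OUT, autosomal and
Z-linked loci, hemizygous females on Z, a reduced Z:A ratio of effective
population size (rho), male-biased mutation on Z (alpha), and optional recent
gene flow from P3 into P2.

Each locus is an independent neutral coalescent genealogy (no within-locus
recombination), simulated with msprime. Z-linked inheritance is represented
by its effect on the coalescent: Z loci evolve in a population of size
rho * Ne with mutation rate alpha * mu, and each female contributes a single
sampled lineage. Linked selection, gBGC and within-locus recombination of
real data are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .core import ABSENT, AUTOSOME, ZCHROM, GenotypeMatrix

INGROUP_POPS = ("P1", "P2", "P3", "P4")
OUTGROUP = "OUT"
ALL_POPS = INGROUP_POPS + (OUTGROUP,)

_NUCS = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Demographic and mutational parameters of the generator.

    Defaults reflect a flycatcher-like setting: diploid Ne of 1e5 per
    population, mu = 4.6e-9 per site per generation, Z:A effective-size ratio
    rho = 0.75 (the neutral expectation with equal breeding sex numbers),
    male-bias factor alpha = 1.1 on the Z mutation rate, sister-pair splits
    within the last few hundred thousand generations and a deeper outgroup.
    """

    n_autosomal_loci: int = 100
    n_z_loci: int = 100
    locus_length: int = 2_000
    locus_spacing: int = 200_000
    ne_autosomal: float = 100_000.0
    z_a_ratio: float = 0.75
    male_bias: float = 1.1
    mu: float = 4.6e-9
    # generations for the P1/P2 split, P3/P4 split, cross-pair split, outgroup
    split_times: tuple = (100_000.0, 150_000.0, 300_000.0, 600_000.0)
    migration_rate: float = 0.0
    migration_rate_z: float | None = None
    samples_per_pop: int = 4
    sexes_per_pop: tuple | None = None
    seed: int = 1

    def __post_init__(self):
        if not 0 < self.z_a_ratio <= 9 / 8:
            raise ValueError("z_a_ratio must lie in (0, 9/8]")
        if self.male_bias < 1:
            raise ValueError("male_bias must be >= 1")
        for name in ("n_autosomal_loci", "n_z_loci", "locus_length",
                     "locus_spacing", "samples_per_pop", "ne_autosomal", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.locus_spacing < self.locus_length:
            raise ValueError("locus_spacing must be >= locus_length")
        t12, t34, tx, tout = self.split_times
        if not (0 < t12 < tx < tout and 0 < t34 < tx):
            raise ValueError("split_times must satisfy 0 < t12,t34 < t_cross < t_out")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be >= 0")
        if self.sexes_per_pop is not None:
            if len(self.sexes_per_pop) != self.samples_per_pop:
                raise ValueError("sexes_per_pop length must equal samples_per_pop")
            if any(s not in ("M", "F") for s in self.sexes_per_pop):
                raise ValueError("sexes must be 'M' or 'F'")

    @property
    def sexes(self) -> tuple:
        if self.sexes_per_pop is not None:
            return tuple(self.sexes_per_pop)
        return tuple("M" if i % 2 == 0 else "F" for i in range(self.samples_per_pop))


@dataclass
class SimTruth:
    """Known ground truth for a simulated dataset."""

    config: SimConfig
    expected_pi: dict
    realized_pi: pd.DataFrame
    expected_d_sign: int
    site_locus: np.ndarray = field(repr=False, default=None)


def _demography(config: SimConfig, ne: float, ploidy_factor: float,
                migration: float) -> msprime.Demography:
    """Five-population split topology (((P1,P2),(P3,P4)),OUT).

    `ploidy_factor` rescales population sizes so that a ploidy-1 ancestry
    model (used for Z) has pairwise coalescence rate 1/(2*rho*Ne).
    """
    t12, t34, tx, tout = config.split_times
    size = ne * ploidy_factor
    dem = msprime.Demography()
    for pop in ALL_POPS:
        dem.add_population(name=pop, initial_size=size)
    for anc in ("ANC12", "ANC34", "ANC", "ROOT"):
        dem.add_population(name=anc, initial_size=size)
    if migration > 0:
        # forward-time P3 -> P2 gene flow == backwards-time lineage movement P2 -> P3
        dem.set_migration_rate(source="P2", dest="P3", rate=migration)
    dem.add_population_split(time=t12, derived=["P1", "P2"], ancestral="ANC12")
    dem.add_population_split(time=t34, derived=["P3", "P4"], ancestral="ANC34")
    dem.add_population_split(time=tx, derived=["ANC12", "ANC34"], ancestral="ANC")
    dem.add_population_split(time=tout, derived=["ANC", OUTGROUP], ancestral="ROOT")
    dem.sort_events()
    return dem


def _seed_stream(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 2)) + 1 for c in ss.spawn(n)]


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for pop in ALL_POPS:
        for i, sex in enumerate(config.sexes):
            rows.append((f"{pop}_{i}", pop, sex))
    df = pd.DataFrame(rows, columns=["sample", "population", "sex"])
    return df.set_index("sample")


def _simulate_class(config: SimConfig, chrom_class: str, n_loci: int,
                    samples_df: pd.DataFrame, anc_seed: int, mut_seed: int):
    """Yield per-locus genotype arrays of shape (n_var, n_samples, 2)."""
    n_samples = len(samples_df)
    sexes = samples_df["sex"].to_numpy()
    if chrom_class == AUTOSOME:
        dem = _demography(config, config.ne_autosomal, 1.0, config.migration_rate)
        sample_sets = {pop: config.samples_per_pop for pop in ALL_POPS}
        ploidy = 2
        rate = config.mu
    else:
        mig = config.migration_rate if config.migration_rate_z is None else config.migration_rate_z
        dem = _demography(config, config.z_a_ratio * config.ne_autosomal, 2.0, mig)
        n_lineages = sum(2 if s == "M" else 1 for s in config.sexes)
        sample_sets = {pop: n_lineages for pop in ALL_POPS}
        ploidy = 1
        rate = config.male_bias * config.mu

    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        ploidy=ploidy,
        sequence_length=config.locus_length,
        recombination_rate=0,
        num_replicates=n_loci,
        random_seed=anc_seed,
    )
    mut_seeds = _seed_stream(mut_seed, n_loci)
    for rep_i, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=rate, random_seed=mut_seeds[rep_i],
            model=msprime.BinaryMutationModel(), discrete_genome=True,
        )
        gm = mts.genotype_matrix()  # (n_var, n_lineages_total) allele indices
        positions = np.array([int(s.position) for s in mts.sites()])
        n_var = gm.shape[0]
        out = np.full((n_var, n_samples, 2), ABSENT, dtype=np.int8)
        if ploidy == 2:
            for j in range(n_samples):
                out[:, j, 0] = gm[:, 2 * j]
                out[:, j, 1] = gm[:, 2 * j + 1]
        else:
            col = 0
            for j in range(n_samples):
                if sexes[j] == "M":
                    out[:, j, 0] = gm[:, col]
                    out[:, j, 1] = gm[:, col + 1]
                    col += 2
                else:
                    out[:, j, 0] = gm[:, col]
                    col += 1
        # drop sites rendered invariant by recurrent mutation
        keep = np.array(
            [len(set(row[row >= 0])) == 2 for row in out.reshape(n_var, -1)],
            dtype=bool,
        ) if n_var else np.zeros(0, dtype=bool)
        yield positions[keep], out[keep]


def simulate_dataset(config: SimConfig):
    """Simulate a full dataset; returns ``(GenotypeMatrix, SimTruth)``."""
    samples_df = _sample_table(config)
    seeds = _seed_stream(config.seed, 5)
    chrom_of = {AUTOSOME: "A1", ZCHROM: "Z1"}

    site_rows = []
    allele_blocks = []
    locus_ids = []
    callable_intervals = {}
    specs = [
        (AUTOSOME, config.n_autosomal_loci, seeds[0], seeds[1]),
        (ZCHROM, config.n_z_loci, seeds[2], seeds[3]),
    ]
    for chrom_class, n_loci, s_anc, s_mut in specs:
        chrom = chrom_of[chrom_class]
        callable_intervals[chrom] = np.array(
            [[j * config.locus_spacing, j * config.locus_spacing + config.locus_length]
             for j in range(n_loci)], dtype=np.int64,
        )
        for locus, (positions, block) in enumerate(
            _simulate_class(config, chrom_class, n_loci, samples_df, s_anc, s_mut)
        ):
            offset = locus * config.locus_spacing
            for k, pos in enumerate(positions):
                site_rows.append((chrom, offset + pos))
            allele_blocks.append(block)
            locus_ids.extend([(chrom_class, locus)] * len(positions))

    alleles = (np.concatenate(allele_blocks, axis=0) if allele_blocks
               else np.zeros((0, len(samples_df), 2), dtype=np.int8))
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos"])

    # assign ancestral (REF) and derived (ALT) nucleotides per site
    rng = np.random.default_rng(seeds[4])
    ref_idx = rng.integers(0, 4, size=len(sites))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(sites))) % 4
    sites["ref"] = _NUCS[ref_idx] if len(sites) else np.array([], dtype=object)
    sites["alt"] = _NUCS[alt_idx] if len(sites) else np.array([], dtype=object)
    sites["locus"] = [l for _, l in locus_ids]

    chrom_class_map = {"A1": AUTOSOME, "Z1": ZCHROM}
    contig_lengths = {
        "A1": config.n_autosomal_loci * config.locus_spacing,
        "Z1": config.n_z_loci * config.locus_spacing,
    }
    matrix = GenotypeMatrix(
        samples=samples_df,
        sites=sites,
        alleles=alleles,
        chrom_class=chrom_class_map,
        contig_lengths=contig_lengths,
        callable_intervals=callable_intervals,
    )

    expected_pi = {
        AUTOSOME: 4 * config.ne_autosomal * config.mu,
        ZCHROM: 4 * (config.z_a_ratio * config.ne_autosomal) * (config.male_bias * config.mu),
    }
    realized = _realized_pi(matrix, config)
    truth = SimTruth(
        config=config,
        expected_pi=expected_pi,
        realized_pi=realized,
        expected_d_sign=int(config.migration_rate > 0 or (config.migration_rate_z or 0) > 0),
        site_locus=sites["locus"].to_numpy(),
    )
    return matrix, truth


def _realized_pi(matrix: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    cls = matrix.site_class()
    rows = []
    L = {AUTOSOME: config.n_autosomal_loci * config.locus_length,
         ZCHROM: config.n_z_loci * config.locus_length}
    for pop in ALL_POPS:
        idx = matrix.sample_indices(population=pop)
        p = matrix.alt_freq(idx)
        for chrom_class in (AUTOSOME, ZCHROM):
            sel = (cls == chrom_class) & ~np.isnan(p)
            pi = float(np.sum(2 * p[sel] * (1 - p[sel])) / L[chrom_class])
            rows.append((pop, chrom_class, pi))
    return pd.DataFrame(rows, columns=["population", "chrom_class", "pi"])


def attach_read_metrics(matrix: GenotypeMatrix, seed: int,
                        mean_depth: float = 30.0, gq_low_fraction: float = 0.0):
    """Attach plausible per-genotype depth and GQ arrays (in place).

    Depth is Poisson(mean_depth); GQ is 99 except for a `gq_low_fraction`
    of genotypes drawn uniformly from [0, 40). Absent hemizygous slots share
    the values of their primary slot.
    """
    rng = np.random.default_rng(seed)
    shape = (matrix.n_sites, matrix.n_samples)
    matrix.depth = rng.poisson(mean_depth, size=shape).astype(np.int32)
    gq = np.full(shape, 99, dtype=np.int32)
    if gq_low_fraction > 0:
        low = rng.random(shape) < gq_low_fraction
        gq[low] = rng.integers(0, 40, size=int(low.sum()))
    matrix.gq = gq
    return matrix
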