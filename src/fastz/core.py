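"""Core in-memory containers for the pipeline.

The central object is :class:`GenotypeMatrix`: a sites x samples array of
allele calls together with sample metadata (population, sex), a per-contig
chromosome-class map (autosome vs Z) and the callable-site intervals from
which per-site denominators (L) are derived.

Allele encoding in ``alleles`` (int8, shape ``(n_sites, n_samples, 2)``):

* ``0`` reference allele, ``1`` alternate allele,
* ``-1`` missing call,
* ``-2`` structurally absent slot -- the second slot of a hemizygous female
  genotype on the Z chromosome (ZW females carry a single Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import intervals as iv

AUTOSOME = "autosome"
ZCHROM = "Z"

MISSING = -1
ABSENT = -2


@dataclass
class GenotypeMatrix:
    samples: pd.DataFrame
    sites: pd.DataFrame
    alleles: np.ndarray
    chrom_class: dict
    contig_lengths: dict
    callable_intervals: dict = field(default_factory=dict)
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        if self.alleles.shape[:2] != (len(self.sites), len(self.samples)):
            raise ValueError("alleles shape does not match sites x samples")
        for col in ("population", "sex"):
            if col not in self.samples.columns:
                raise ValueError(f"sample table lacks '{col}' column")

    # -- basic introspection -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_class(self) -> np.ndarray:
        """Chromosome class ('autosome' | 'Z') per site."""
        return self.sites["chrom"].map(self.chrom_class).to_numpy()

    def sample_indices(self, population=None, samples=None) -> np.ndarray:
        if samples is not None:
            pos = {name: i for i, name in enumerate(self.samples.index)}
            return np.asarray([pos[s] for s in samples], dtype=np.intp)
        if population is None:
            return np.arange(self.n_samples, dtype=np.intp)
        pops = [population] if isinstance(population, str) else list(population)
        mask = self.samples["population"].isin(pops).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"no samples for population(s) {pops}")
        return idx

    # -- allele summaries ----------------------------------------------------

    def allele_counts(self, sample_idx=None) -> np.ndarray:
        """Per-site (ref_count, alt_count) over non-missing calls."""
        a = self.alleles if sample_idx is None else self.alleles[:, sample_idx, :]
        ref = (a == 0).sum(axis=(1, 2))
        alt = (a == 1).sum(axis=(1, 2))
        return np.stack([ref, alt], axis=1)

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        """Alternate-allele frequency per site; NaN where no calls."""
        ac = self.allele_counts(sample_idx)
        tot = ac.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, ac[:, 1] / tot, np.nan)

    # -- restructuring -------------------------------------------------------

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            alleles=self.alleles[idx],
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            sites=self.sites.copy(),
            alleles=self.alleles.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            gq=None if self.gq is None else self.gq.copy(),
        )


@dataclass
class CallableLedger:
    """Counts of callable sites (the L denominators of per-site statistics).

    ``counts`` maps chromosome class -> number of callable bases. The ledger
    is shared across populations: the site-level filters (missingness in any
    species, repeats, female heterozygosity) remove whole sites.
    """

    counts: dict

    def L(self, chrom_class: str) -> int:
        return int(self.counts[chrom_class])

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix) -> "CallableLedger":
        counts = {AUTOSOME: 0, ZCHROM: 0}
        for chrom, ivs in matrix.callable_intervals.items():
            counts[matrix.chrom_class[chrom]] += iv.total_span(ivs)
        return cls(counts=counts)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom_class": list(self.counts), "callable_sites": list(self.counts.values())}
        )


def validate_sex_labels(matrix: GenotypeMatrix) -> None:
    """Z-linked data require every sample to carry an M/F sex label."""
    has_z = any(c == ZCHROM for c in matrix.chrom_class.values())
    bad = ~matrix.samples["sex"].isin(["M", "F"])
    if has_z and bad.any():
        names = list(matrix.samples.index[bad])
        raise ValueError(f"samples without valid sex label on Z-linked data: {names}")
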