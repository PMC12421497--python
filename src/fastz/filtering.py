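"""Genotype- and site-level filters with Z-specific, sex-aware rules.

The genotype stage removes individual calls failing depth or genotype-quality
thresholds (GQ thresholds differ between autosomes and the Z, and on the Z
between males and hemizygous females). The site stage then removes whole
sites: Z sites with any remaining heterozygous female call (biological
artifacts in a ZW system), sites exceeding the per-species missingness cap,
and sites inside the repeat mask. Bounds are exclusive as stated: depth
below ``min_depth`` or above ``max_depth`` fails; a call is kept only with
GQ strictly greater than its threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .core import (AUTOSOME, MISSING, ZCHROM, CallableLedger,
                   GenotypeMatrix, validate_sex_labels)


@dataclass
class FilterConfig:
    min_depth: int = 5
    max_depth: int = 200
    gq_autosome: int = 30
    gq_z_male: int = 30
    gq_z_female: int = 15
    max_missing_fraction: float = 0.10
    repeat_mask: dict = field(default_factory=dict)  # chrom -> (n,2) intervals
    # populations over which the missingness rule applies; None = all
    missingness_populations: tuple | None = None

    def __post_init__(self):
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be < max_depth")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must lie in [0, 1]")


def filter_genotypes(matrix: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Set genotypes failing depth or sex/chromosome GQ thresholds to missing."""
    if matrix.depth is None or matrix.gq is None:
        raise ValueError("per-genotype depth and GQ are required for genotype filtering")
    validate_sex_labels(matrix)
    out = matrix.copy()
    is_z = (out.site_class() == ZCHROM)[:, None]
    female = (out.samples["sex"] == "F").to_numpy()[None, :]

    gq_threshold = np.where(is_z, np.where(female, cfg.gq_z_female, cfg.gq_z_male),
                            cfg.gq_autosome)
    fail = ((out.depth < cfg.min_depth) | (out.depth > cfg.max_depth)
            | (out.gq <= gq_threshold))
    called = out.alleles >= 0
    out.alleles[called & fail[:, :, None]] = MISSING
    return out


def _missing_fraction(matrix: GenotypeMatrix, pop_idx: np.ndarray) -> np.ndarray:
    """Per-site fraction of samples in `pop_idx` with no surviving call."""
    a = matrix.alleles[:, pop_idx, :]
    has_call = (a >= 0).any(axis=2)
    return 1.0 - has_call.mean(axis=1)


def filter_sites(matrix: GenotypeMatrix, cfg: FilterConfig):
    """Apply site-level filters; returns ``(matrix, CallableLedger)``.

    The ledger counts callable bases per chromosome class: the callable span
    minus repeat-masked bases minus variant sites removed by the
    female-heterozygosity and missingness rules.
    """
    validate_sex_labels(matrix)
    n = matrix.n_sites
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()

    # (a) Z sites with any heterozygous female genotype remaining
    is_z = matrix.site_class() == ZCHROM
    female_idx = np.flatnonzero((matrix.samples["sex"] == "F").to_numpy())
    fa = matrix.alleles[:, female_idx, :]
    het_female = ((fa[:, :, 0] >= 0) & (fa[:, :, 1] >= 0)
                  & (fa[:, :, 0] != fa[:, :, 1])).any(axis=1)
    drop_het = is_z & het_female

    # (b) missingness per population
    pops = (cfg.missingness_populations
            or tuple(matrix.samples["population"].unique()))
    drop_miss = np.zeros(n, dtype=bool)
    for pop in pops:
        idx = matrix.sample_indices(population=pop)
        drop_miss |= _missing_fraction(matrix, idx) > cfg.max_missing_fraction

    # (c) repeat overlap
    drop_repeat = np.zeros(n, dtype=bool)
    known = set(matrix.contig_lengths)
    for chrom, mask_iv in cfg.repeat_mask.items():
        if chrom not in known:
            import warnings
            warnings.warn(f"repeat intervals on unknown contig {chrom!r} ignored")
            continue
        sel = chroms == chrom
        drop_repeat[sel] = iv.contains(mask_iv, pos[sel])

    keep = ~(drop_het | drop_miss | drop_repeat)
    filtered = matrix.subset_sites(keep)

    # ledger: remove repeat-masked spans and every dropped variant position
    # from the callable intervals, so the denominators stay consistent under
    # re-filtering
    removed = ~keep
    counts = {AUTOSOME: 0, ZCHROM: 0}
    new_callable = {}
    for chrom, ivs in matrix.callable_intervals.items():
        cut = [cfg.repeat_mask[chrom]] if chrom in cfg.repeat_mask else []
        dropped_pos = pos[removed & (chroms == chrom)]
        if dropped_pos.size:
            cut.append(np.stack([dropped_pos, dropped_pos + 1], axis=1))
        left = iv.subtract(ivs, np.concatenate(cut)) if cut else iv.merge(ivs)
        new_callable[chrom] = left
        counts[matrix.chrom_class[chrom]] += iv.total_span(left)
    filtered.callable_intervals = new_callable

    ledger = CallableLedger(counts=counts)
    ledger.report = pd.DataFrame(
        {"rule": ["female_heterozygous_z", "missingness", "repeat_overlap", "retained"],
         "sites": [int(drop_het.sum()), int((drop_miss & ~drop_het).sum()),
                   int((drop_repeat & ~drop_het & ~drop_miss).sum()), int(keep.sum())]}
    )
    return filtered, ledger
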