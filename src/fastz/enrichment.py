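"""Fixed differences, shared polymorphisms, functional densities, sweep
overlap, and the 2x2 Fisher-exact Z-versus-autosome enrichment tests.

A site is a fixed difference between two species when each species is fixed
(no alternative allele among its non-missing calls) for a different allele,
and a shared polymorphism when it segregates within both. The enrichment
tests contrast counts of flagged versus unflagged 200-kb windows between
autosomes and the Z chromosome; the reported odds ratio is the sample
cross-product (a*d)/(b*c) with a two-sided Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import intervals as iv
from .core import GenotypeMatrix

CATEGORY_PRECEDENCE = ("zero-fold", "four-fold", "UTR", "CNE", "intron", "intergenic")


def classify_sites(matrix: GenotypeMatrix, pop_a, pop_b) -> pd.DataFrame:
    """Per-site status for a species pair: fixed_difference,
    shared_polymorphism, private, other, or untyped."""
    ia = matrix.sample_indices(population=pop_a)
    ib = matrix.sample_indices(population=pop_b)
    aca = matrix.allele_counts(ia)
    acb = matrix.allele_counts(ib)

    def states(ac):
        has_ref = ac[:, 0] > 0
        has_alt = ac[:, 1] > 0
        typed = has_ref | has_alt
        seg = has_ref & has_alt
        fixed_ref = has_ref & ~has_alt
        fixed_alt = has_alt & ~has_ref
        return typed, seg, fixed_ref, fixed_alt

    ta, sa, fra, faa = states(aca)
    tb, sb, frb, fab = states(acb)
    status = np.full(matrix.n_sites, "other", dtype=object)
    status[~(ta & tb)] = "untyped"
    fixed_diff = (fra & fab) | (faa & frb)
    shared = sa & sb
    private = (sa ^ sb) & ta & tb
    status[ta & tb & private] = "private"
    status[shared] = "shared_polymorphism"
    status[fixed_diff] = "fixed_difference"
    out = matrix.sites[["chrom", "pos"]].copy()
    out["chrom_class"] = matrix.site_class()
    out["status"] = status
    return out


def assign_functional_category(sites: pd.DataFrame, annotations: dict,
                               degeneracy: pd.DataFrame | None = None) -> pd.Series:
    """One functional category per site under the fixed precedence
    zero-fold/four-fold > UTR > CNE > intron > intergenic.

    ``annotations`` maps category name ('UTR', 'CNE', 'intron') to
    {chrom: intervals}; degeneracy classes come from the coding table.
    """
    cat = np.full(len(sites), "intergenic", dtype=object)
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    for name in ("intron", "CNE", "UTR"):  # ascending precedence
        per_chrom = annotations.get(name, {})
        for chrom, ivs in per_chrom.items():
            on = chroms == chrom
            hit = iv.contains(ivs, pos[on])
            sub = cat[on]
            sub[hit] = name
            cat[on] = sub
    if degeneracy is not None:
        key = sites[["chrom", "pos"]].merge(
            degeneracy[["chrom", "pos", "degeneracy"]].drop_duplicates(["chrom", "pos"]),
            on=["chrom", "pos"], how="left")["degeneracy"]
        coding = key.isin(["zero-fold", "four-fold"]).to_numpy()
        cat[coding] = key.to_numpy()[coding]
    return pd.Series(cat, index=sites.index, name="category")


def functional_density(classified: pd.DataFrame, callable_by_category: dict) -> pd.DataFrame:
    """Fixed-difference density and proportion per (chromosome class, category).

    ``callable_by_category`` maps (chrom_class, category) -> callable sites.
    Density is NaN where the category has no callable sites.
    """
    fixed = classified[classified["status"] == "fixed_difference"]
    rows = []
    for (cls, cat), L in callable_by_category.items():
        n = int(((fixed["chrom_class"] == cls) & (fixed["category"] == cat)).sum())
        dens = n / L if L > 0 else np.nan
        rows.append((cls, cat, n, L, dens))
    out = pd.DataFrame(rows, columns=["chrom_class", "category", "n_fixed",
                                      "callable", "density"])
    totals = out.groupby("chrom_class")["n_fixed"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["proportion"] = np.where(totals > 0, out["n_fixed"] / totals, np.nan)
    return out


def sweep_overlap(nonsyn_fixed: pd.DataFrame, regions) -> pd.DataFrame:
    """Fraction of sweep regions containing >= 1 nonsynonymous fixed
    difference, with per-sweep counts. Empty inputs give an empty report."""
    rows = []
    for r in regions:
        on = nonsyn_fixed[nonsyn_fixed["chrom"] == r.chrom]
        n = int(((on["pos"] >= r.start) & (on["pos"] <= r.end)).sum())
        rows.append((r.chrom, r.start, r.end, n))
    per_sweep = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_nonsyn_fixed"])
    return per_sweep


def sweep_overlap_fraction(per_sweep: pd.DataFrame) -> float:
    if len(per_sweep) == 0:
        return 0.0
    return float((per_sweep["n_nonsyn_fixed"] >= 1).mean())


@dataclass
class ContingencyTable:
    """2x2 counts; rows autosome/Z, columns flagged/not-flagged."""

    autosome_flagged: int
    z_flagged: int
    autosome_not: int
    z_not: int

    def __post_init__(self):
        if min(self.autosome_flagged, self.z_flagged,
               self.autosome_not, self.z_not) < 0:
            raise ValueError("contingency counts must be non-negative")
        rows = (self.autosome_flagged + self.z_flagged,
                self.autosome_not + self.z_not)
        cols = (self.autosome_flagged + self.autosome_not,
                self.z_flagged + self.z_not)
        if min(*rows, *cols) == 0:
            raise ValueError("contingency table margins must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.autosome_flagged, self.z_flagged],
                         [self.autosome_not, self.z_not]])


def fisher_enrichment(table: ContingencyTable):
    """(sample odds ratio, Fisher exact p).

    OR = (a*d)/(b*c) on the [[a, b], [c, d]] layout. A zero off-diagonal cell
    makes the OR infinite and the p-value one-sided (alternative 'greater').
    """
    arr = table.as_array()
    a, b = arr[0]
    c, d = arr[1]
    if b * c == 0:
        _, p = sps.fisher_exact(arr, alternative="greater")
        return float("inf"), float(p)
    odds = (a * d) / (b * c)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)
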