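"""Ancestral-allele assignment by the two-of-three fixed-group rule.

Three sample groups (an outgroup and the two ingroup sister pairs) vote:
an allele is called ancestral when at least two groups are fixed for it.
A group is "fixed" when it has at least ``min_calls`` non-missing allele
observations and no alternative allele among them. Variable sites that
cannot be polarized are masked in the ancestralized reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .core import GenotypeMatrix


@dataclass
class PolarizationGroups:
    outgroup: list
    group2: list
    group3: list

    def __post_init__(self):
        sets = [set(self.outgroup), set(self.group2), set(self.group3)]
        if any(len(s) == 0 for s in sets):
            raise ValueError("all three polarization groups must be non-empty")
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("polarization groups must be disjoint")

    @classmethod
    def from_populations(cls, samples: pd.DataFrame, outgroup, pair2, pair3):
        def members(pops):
            pops = [pops] if isinstance(pops, str) else list(pops)
            return list(samples.index[samples["population"].isin(pops)])
        return cls(members(outgroup), members(pair2), members(pair3))


def polarize_sites(matrix: GenotypeMatrix, groups: PolarizationGroups,
                   min_calls: int = 1) -> pd.DataFrame:
    """Label every site ancestral=allele or unpolarized.

    Returns a table aligned with ``matrix.sites``: columns chrom, pos,
    ancestral (base or '.'), ancestral_is_ref, status, n_support.
    """
    votes_ref = np.zeros(matrix.n_sites, dtype=np.int8)
    votes_alt = np.zeros(matrix.n_sites, dtype=np.int8)
    for members in (groups.outgroup, groups.group2, groups.group3):
        idx = matrix.sample_indices(samples=members)
        ac = matrix.allele_counts(idx)
        votes_ref += ((ac[:, 0] >= min_calls) & (ac[:, 1] == 0)).astype(np.int8)
        votes_alt += ((ac[:, 1] >= min_calls) & (ac[:, 0] == 0)).astype(np.int8)

    total = matrix.allele_counts()
    anc_ref = votes_ref >= 2
    anc_alt = votes_alt >= 2
    # monomorphic across every non-missing call: trivially polarized
    anc_ref |= (total[:, 1] == 0) & (total[:, 0] > 0)
    anc_alt |= (total[:, 0] == 0) & (total[:, 1] > 0)

    ref = matrix.sites["ref"].to_numpy()
    alt = matrix.sites["alt"].to_numpy()
    ancestral = np.where(anc_ref, ref, np.where(anc_alt, alt, "."))
    status = np.where(anc_ref | anc_alt, "polarized", "unpolarized")
    return pd.DataFrame({
        "chrom": matrix.sites["chrom"],
        "pos": matrix.sites["pos"],
        "ancestral": ancestral,
        "ancestral_is_ref": anc_ref,
        "status": status,
        "n_support": np.where(anc_ref, votes_ref, np.where(anc_alt, votes_alt, 0)),
    })


def polarize_by_outgroup(matrix: GenotypeMatrix, outgroup,
                         min_calls: int = 1) -> pd.DataFrame:
    """Polarize by outgroup fixation alone (for four-taxon tests).

    The derived state at a site is the allele absent from the outgroup
    sample(s); sites where the outgroup is not fixed are unpolarized. This is
    the appropriate rule for ABBA/BABA-type quartets, where the two-of-three
    group vote would discard exactly the sites segregating in two ingroups.
    ``outgroup`` is a population label or list of labels (combined).
    """
    idx = matrix.sample_indices(population=outgroup)
    ac = matrix.allele_counts(idx)
    anc_ref = (ac[:, 0] >= min_calls) & (ac[:, 1] == 0)
    anc_alt = (ac[:, 1] >= min_calls) & (ac[:, 0] == 0)
    ref = matrix.sites["ref"].to_numpy()
    alt = matrix.sites["alt"].to_numpy()
    return pd.DataFrame({
        "chrom": matrix.sites["chrom"],
        "pos": matrix.sites["pos"],
        "ancestral": np.where(anc_ref, ref, np.where(anc_alt, alt, ".")),
        "ancestral_is_ref": anc_ref,
        "status": np.where(anc_ref | anc_alt, "polarized", "unpolarized"),
        "n_support": (anc_ref | anc_alt).astype(int),
    })


def derived_allele_frequency(matrix: GenotypeMatrix, calls: pd.DataFrame,
                             sample_idx) -> np.ndarray:
    """Per-site derived (non-ancestral) allele frequency; NaN if unpolarized."""
    p_alt = matrix.alt_freq(sample_idx)
    polarized = (calls["status"] == "polarized").to_numpy()
    anc_is_ref = calls["ancestral_is_ref"].to_numpy()
    out = np.where(anc_is_ref, p_alt, 1.0 - p_alt)
    out[~polarized] = np.nan
    return out


def build_ancestral_sequence(reference: dict, calls: pd.DataFrame,
                             genotyped_intervals: dict, mask_char: str = "N") -> dict:
    """Ancestralize a reference: mask non-genotyped and unpolarized positions,
    substitute ancestral alleles elsewhere."""
    out = {}
    for chrom, seq in reference.items():
        arr = np.full(len(seq), mask_char, dtype="U1")
        for s, e in iv.merge(genotyped_intervals.get(chrom, [])):
            if e > len(seq):
                raise ValueError(f"genotyped interval beyond reference length on {chrom}")
            arr[s:e] = list(seq[s:e])
        out[chrom] = arr
    for _, row in calls.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in out:
            continue
        if pos >= len(out[chrom]):
            raise ValueError(f"call at {chrom}:{pos} beyond reference length")
        if out[chrom][pos] == mask_char:
            continue  # not genotyped
        out[chrom][pos] = row["ancestral"] if row["status"] == "polarized" else mask_char
    return {c: "".join(a) for c, a in out.items()}
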