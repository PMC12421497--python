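"""Selection on protein-coding sequence: degeneracy classes, pi_N/pi_S,
GC-weighted d_N/d_S aggregation, and unfolded site frequency spectra.

Degeneracy is taken from the standard nuclear code: a CDS base is zero-fold
degenerate when every substitution changes the amino acid and four-fold when
none does. pi_N/pi_S contrasts per-site diversity at zero-fold versus
four-fold sites (GC-conservative SNPs only by default, to exclude sites
subject to GC-biased gene conversion). Divergence counts per gene are pooled
with GC/AT weighting: each GC-conservative substitution class is normalised
by the fraction of sites able to undergo it (S-to-S counts by f_GC, W-to-W by
f_AT) and the two classes summed; the alternative multiplicative weighting is
available behind a flag. Confidence intervals resample genes with
replacement (100 replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .core import GenotypeMatrix
from .diversity import gc_conservative

ZERO_FOLD = "zero-fold"
FOUR_FOLD = "four-fold"
OTHER = "other"

_BASES = "ACGT"


def _degeneracy_lookup() -> dict:
    """(codon, codon_pos) -> class, from the standard nuclear code."""
    table = CodonTable.unambiguous_dna_by_id[1]

    def aa(codon):
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    lut = {}
    for c0 in _BASES:
        for c1 in _BASES:
            for c2 in _BASES:
                codon = c0 + c1 + c2
                ref_aa = aa(codon)
                for pos in range(3):
                    nonsyn = 0
                    for b in _BASES:
                        if b == codon[pos]:
                            continue
                        alt = codon[:pos] + b + codon[pos + 1:]
                        if aa(alt) != ref_aa:
                            nonsyn += 1
                    lut[(codon, pos)] = (ZERO_FOLD if nonsyn == 3
                                         else FOUR_FOLD if nonsyn == 0 else OTHER)
    return lut


_LUT = _degeneracy_lookup()


@dataclass
class CodingSequence:
    """A spliced CDS in reading orientation with its genomic coordinates.

    ``positions[i]`` is the genomic (0-based) position of CDS base i.
    """

    gene: str
    chrom: str
    positions: np.ndarray
    seq: str

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.seq = self.seq.upper()
        if len(self.positions) != len(self.seq):
            raise ValueError(f"{self.gene}: positions/sequence length mismatch")


@dataclass
class GeneSubstitutionCounts:
    """Per-gene substitution counts split into GC-conservative categories."""

    gene: str
    nonsyn_ss: float
    nonsyn_ww: float
    syn_ss: float
    syn_ww: float
    l_nonsyn: float
    l_syn: float
    f_gc: float

    def __post_init__(self):
        for name in ("nonsyn_ss", "nonsyn_ww", "syn_ss", "syn_ww", "l_nonsyn", "l_syn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.f_gc <= 1:
            raise ValueError("f_gc must lie in [0, 1]")


@dataclass
class SelectionSummary:
    value: float
    kind: str
    chrom_class: str | None = None
    ci: tuple | None = None


def classify_degeneracy(cds_list) -> pd.DataFrame:
    """Label every CDS base; genes with internal stops are flagged and skipped.

    Trailing bases beyond the last complete codon are trimmed. Returns columns
    chrom, pos, gene, codon_pos, degeneracy.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    rows = []
    for cds in cds_list:
        n = (len(cds.seq) // 3) * 3
        codons = [cds.seq[i:i + 3] for i in range(0, n, 3)]
        if any(c in table.stop_codons for c in codons[:-1]):
            import warnings
            warnings.warn(f"gene {cds.gene} has an internal stop codon; skipped")
            continue
        for ci, codon in enumerate(codons):
            if any(b not in _BASES for b in codon):
                continue
            for k in range(3):
                rows.append((cds.chrom, int(cds.positions[3 * ci + k]), cds.gene,
                             k, _LUT[(codon, k)]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene", "codon_pos", "degeneracy"])


def read_cds_from_gff(gff_path, fasta_path) -> list:
    """Extract spliced CDS records from GFF3 + FASTA.

    Per gene, the transcript with the longest summed CDS is used. Minus-strand
    CDS are reverse-complemented with genomic positions in reading order.
    """
    import gffutils
    from Bio import SeqIO
    from Bio.Seq import Seq

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    out = []
    for gene in db.features_of_type("gene"):
        best = None
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            length = sum(c.end - c.start + 1 for c in cds)
            if cds and (best is None or length > best[1]):
                best = (cds, length)
        if best is None:
            continue
        cds = best[0]
        chrom = cds[0].seqid
        positions = np.concatenate([np.arange(c.start - 1, c.end) for c in cds])
        seq = "".join(seqs[chrom][c.start - 1:c.end] for c in cds)
        if cds[0].strand == "-":
            positions = positions[::-1]
            seq = str(Seq(seq).reverse_complement())
        out.append(CodingSequence(gene.id, chrom, positions, seq))
    return out


def _class_diversity(matrix, deg_table, population, gc_only, degeneracy):
    """Per-gene (sum 2pq, n_sites) for one degeneracy class."""
    sub = deg_table[deg_table["degeneracy"] == degeneracy]
    idx = matrix.sample_indices(population=population) if population else None
    p = matrix.alt_freq(idx)
    keep = ~np.isnan(p) & (p > 0) & (p < 1)
    if gc_only:
        keep &= gc_conservative(matrix.sites["ref"], matrix.sites["alt"])
    var = matrix.sites.loc[keep, ["chrom", "pos"]].copy()
    var["contrib"] = 2 * p[keep] * (1 - p[keep])
    merged = sub.merge(var, on=["chrom", "pos"], how="left")
    per_gene = merged.groupby("gene").agg(
        contrib=("contrib", lambda x: x.fillna(0).sum()),
        n_sites=("pos", "size"),
    )
    return per_gene


def pi_n_pi_s(matrix: GenotypeMatrix, deg_table: pd.DataFrame, population=None,
              gc_conservative_only: bool = True, n_boot: int = 100,
              seed=None) -> SelectionSummary:
    """pi at zero-fold sites over pi at four-fold sites, CI over genes."""
    per_n = _class_diversity(matrix, deg_table, population, gc_conservative_only, ZERO_FOLD)
    per_s = _class_diversity(matrix, deg_table, population, gc_conservative_only, FOUR_FOLD)
    genes = sorted(set(per_n.index) | set(per_s.index))
    per_n = per_n.reindex(genes, fill_value=0)
    per_s = per_s.reindex(genes, fill_value=0)

    def ratio(sel):
        num = per_n["contrib"].to_numpy()[sel].sum()
        ln = per_n["n_sites"].to_numpy()[sel].sum()
        den = per_s["contrib"].to_numpy()[sel].sum()
        ls = per_s["n_sites"].to_numpy()[sel].sum()
        if den == 0 or ls == 0 or ln == 0:
            return np.nan
        return (num / ln) / (den / ls)

    point = ratio(np.arange(len(genes)))
    if np.isnan(point):
        raise ValueError("four-fold diversity is zero; pi_N/pi_S undefined")
    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        reps = [ratio(rng.integers(0, len(genes), size=len(genes)))
                for _ in range(n_boot)]
        reps = [r for r in reps if not np.isnan(r)]
        ci = tuple(np.quantile(reps, [0.025, 0.975])) if reps else None
    return SelectionSummary(value=float(point), kind="pi_n_pi_s", ci=ci)


def aggregate_dn_ds(counts, weighting: str = "divide", n_boot: int = 100,
                    seed=None) -> SelectionSummary:
    """Pool per-gene GC-conservative substitution counts into d_N/d_S."""
    if weighting not in ("divide", "multiply"):
        raise ValueError("weighting must be 'divide' or 'multiply'")
    counts = list(counts)
    if not counts:
        raise ValueError("no gene counts supplied")

    def pooled(sel):
        cs = [counts[i] for i in sel]
        l_n = sum(c.l_nonsyn for c in cs)
        l_s = sum(c.l_syn for c in cs)
        tot_len = sum(c.l_nonsyn + c.l_syn for c in cs)
        f_gc = sum((c.l_nonsyn + c.l_syn) * c.f_gc for c in cs) / tot_len
        f_at = 1 - f_gc
        n_ss = sum(c.nonsyn_ss for c in cs)
        n_ww = sum(c.nonsyn_ww for c in cs)
        s_ss = sum(c.syn_ss for c in cs)
        s_ww = sum(c.syn_ww for c in cs)
        if f_gc in (0.0, 1.0):
            if (f_gc == 0.0 and (n_ss or s_ss)) or (f_gc == 1.0 and (n_ww or s_ww)):
                raise ValueError("degenerate GC fraction with opposite-class counts")
        if weighting == "divide":
            dn = (n_ss / f_gc if n_ss else 0.0) / l_n + (n_ww / f_at if n_ww else 0.0) / l_n
            ds = (s_ss / f_gc if s_ss else 0.0) / l_s + (s_ww / f_at if s_ww else 0.0) / l_s
        else:
            dn = (n_ss * f_gc + n_ww * f_at) / l_n
            ds = (s_ss * f_gc + s_ww * f_at) / l_s
        return np.nan if ds == 0 else dn / ds

    point = pooled(range(len(counts)))
    if np.isnan(point):
        raise ValueError("synonymous divergence is zero; d_N/d_S undefined")
    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            try:
                r = pooled(rng.integers(0, len(counts), size=len(counts)))
            except ValueError:
                continue
            if not np.isnan(r):
                reps.append(r)
        ci = tuple(np.quantile(reps, [0.025, 0.975])) if reps else None
    return SelectionSummary(value=float(point), kind="dn_ds", ci=ci)


def build_sfs(matrix: GenotypeMatrix, calls: pd.DataFrame, deg_table: pd.DataFrame,
              population=None, gc_conservative_only: bool = True,
              n_alleles: int | None = None, project: bool = False) -> dict:
    """Unfolded SFS per degeneracy class from polarized sites.

    Classified positions absent from the variant table are monomorphic
    ancestral (bin 0). Sites whose observed allele number differs from the
    spectrum size are hypergeometrically projected down when ``project`` is
    set, otherwise rejected.
    """
    idx = matrix.sample_indices(population=population) if population is not None \
        else np.arange(matrix.n_samples)
    ac = matrix.allele_counts(idx)
    polarized = (calls["status"] == "polarized").to_numpy()
    anc_is_ref = calls["ancestral_is_ref"].to_numpy()
    derived = np.where(anc_is_ref, ac[:, 1], ac[:, 0])
    total = ac.sum(axis=1)

    usable = polarized.copy()
    if gc_conservative_only:
        usable &= gc_conservative(matrix.sites["ref"], matrix.sites["alt"])
    var = matrix.sites.loc[usable, ["chrom", "pos"]].copy()
    var["derived"] = derived[usable]
    var["total"] = total[usable]

    if n_alleles is None:
        n_alleles = int(var["total"].max()) if len(var) else 2 * len(idx)

    out = {}
    from scipy.stats import hypergeom
    for cls_name in (ZERO_FOLD, FOUR_FOLD):
        sub = deg_table[deg_table["degeneracy"] == cls_name]
        merged = sub.merge(var, on=["chrom", "pos"], how="left")
        sfs = np.zeros(n_alleles + 1, dtype=float)
        mono = merged["derived"].isna().sum()
        sfs[0] += mono
        poly = merged.dropna(subset=["derived"])
        for d, t in zip(poly["derived"].astype(int), poly["total"].astype(int)):
            if t == n_alleles:
                sfs[d] += 1
            elif project and t > n_alleles:
                ks = np.arange(0, n_alleles + 1)
                sfs += hypergeom.pmf(ks, t, d, n_alleles)
            else:
                raise ValueError(
                    f"site with {t} alleles cannot fill a {n_alleles}-allele "
                    "spectrum (set project=True to downsample)")
        out[cls_name] = sfs
    return out


def write_sfs(sfs: dict, path) -> None:
    """Whitespace-delimited spectrum file: allele number, then the zero-fold
    (selected) and four-fold (neutral) spectra, one per line."""
    with open(path, "w") as fh:
        n = len(next(iter(sfs.values()))) - 1
        fh.write(f"{n}\n")
        for cls_name in (ZERO_FOLD, FOUR_FOLD):
            fh.write(" ".join(f"{x:g}" for x in sfs[cls_name]) + "\n")
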