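"""File-format boundaries: VCF 4.2, sample metadata TSV, BED, small tables.

Internal coordinates are 0-based half-open; VCF/GFF are converted on the way
in and out. Reading uses pysam; writing emits plain VCF 4.2 text (the
in-memory matrix is already fully normalised, so the writer is a direct
serialisation, verified by round-trip tests through pysam).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from . import intervals as iv
from .core import ABSENT, MISSING, ZCHROM, GenotypeMatrix


def _format_gt(pair) -> str:
    a, b = pair
    first = "." if a == MISSING else str(int(a))
    if b == ABSENT:
        return first
    second = "." if b == MISSING else str(int(b))
    return f"{first}/{second}"


def write_vcf(matrix: GenotypeMatrix, path, all_sites: bool = True,
              seed=None, ancestral=None) -> None:
    """Write the matrix as VCF 4.2.

    With ``all_sites=True`` every callable position is emitted, monomorphic
    positions as REF='N', ALT='.' records, so that per-site denominators can
    be reconstructed from the file alone. Hemizygous genotypes are written
    haploid. ``ancestral``, if given, is a per-variant-site array of
    ancestral alleles written as AA INFO tags (``.`` when unpolarized).
    """
    sites = matrix.sites
    sample_names = list(matrix.samples.index)
    has_dp = matrix.depth is not None
    has_gq = matrix.gq is not None
    fmt_keys = ["GT"] + (["DP"] if has_dp else []) + (["GQ"] if has_gq else [])

    lines = ["##fileformat=VCFv4.2", "##source=fastz"]
    if seed is not None:
        lines.append(f"##fastz_seed={int(seed)}")
    cls_spec = ",".join(f"{c}:{matrix.chrom_class[c]}" for c in sorted(matrix.chrom_class))
    lines.append(f"##fastz_chrom_class={cls_spec}")
    for chrom in sorted(matrix.contig_lengths):
        lines.append(f"##contig=<ID={chrom},length={matrix.contig_lengths[chrom]}>")
    lines.append('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if has_gq:
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names))

    # variant records indexed by (chrom, pos) for interleaving with monomorphs
    variant_pos = {}
    for i in range(matrix.n_sites):
        variant_pos[(sites.at[i, "chrom"], int(sites.at[i, "pos"]))] = i

    def variant_record(i: int) -> str:
        chrom = sites.at[i, "chrom"]
        pos = int(sites.at[i, "pos"])
        info = "."
        if ancestral is not None:
            aa = ancestral[i]
            info = f"AA={aa}" if aa not in (None, "", ".") else "AA=."
        cells = []
        for j in range(matrix.n_samples):
            parts = [_format_gt(matrix.alleles[i, j])]
            if has_dp:
                parts.append(str(int(matrix.depth[i, j])))
            if has_gq:
                parts.append(str(int(matrix.gq[i, j])))
            cells.append(":".join(parts))
        return "\t".join(
            [chrom, str(pos + 1), ".", str(sites.at[i, "ref"]), str(sites.at[i, "alt"]),
             ".", "PASS", info, ":".join(fmt_keys)] + cells
        )

    def monomorphic_record(chrom: str, pos: int) -> str:
        gts = []
        is_z = matrix.chrom_class.get(chrom) == ZCHROM
        female = (matrix.samples["sex"] == "F").to_numpy()
        for j in range(matrix.n_samples):
            gt = "0" if (is_z and female[j]) else "0/0"
            gts.append(":".join([gt] + ["30"] * (has_dp + has_gq)))
        return "\t".join([chrom, str(pos + 1), ".", "N", ".", ".", "PASS", ".",
                          ":".join(fmt_keys)] + gts)

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for chrom in sorted(matrix.contig_lengths):
            if all_sites and chrom in matrix.callable_intervals:
                for s, e in iv.merge(matrix.callable_intervals[chrom]):
                    for pos in range(int(s), int(e)):
                        i = variant_pos.get((chrom, pos))
                        fh.write((variant_record(i) if i is not None
                                  else monomorphic_record(chrom, pos)) + "\n")
            else:
                in_chrom = [i for i in range(matrix.n_sites)
                            if sites.at[i, "chrom"] == chrom]
                for i in sorted(in_chrom, key=lambda k: int(sites.at[k, "pos"])):
                    fh.write(variant_record(i) + "\n")


def read_vcf(path, samples: pd.DataFrame, chrom_class: dict | None = None) -> GenotypeMatrix:
    """Read a (possibly all-sites) VCF back into a GenotypeMatrix.

    ``samples`` is the metadata table (index sample, columns population, sex).
    The chromosome-class map is taken from the ``##fastz_chrom_class`` header
    if not supplied. Callable intervals are the union of all record positions.
    """
    vf = pysam.VariantFile(str(path))
    names = list(vf.header.samples)
    samples = samples.loc[names]
    if chrom_class is None:
        chrom_class = {}
        for rec in str(vf.header).splitlines():
            if rec.startswith("##fastz_chrom_class="):
                for item in rec.split("=", 1)[1].split(","):
                    c, cls = item.split(":")
                    chrom_class[c] = cls
    contig_lengths = {c: vf.header.contigs[c].length or 0 for c in vf.header.contigs}

    site_rows, gts, dps, gqs = [], [], [], []
    covered = {}
    any_dp = any_gq = False
    for rec in vf:
        pos0 = rec.pos - 1
        covered.setdefault(rec.chrom, []).append(pos0)
        alts = [a for a in (rec.alts or []) if a not in (None, ".")]
        if not alts:
            continue
        if len(alts) > 1:
            continue  # biallelic retention only
        row = np.full((len(names), 2), ABSENT, dtype=np.int8)
        dp_row = np.zeros(len(names), dtype=np.int32)
        gq_row = np.zeros(len(names), dtype=np.int32)
        for j, name in enumerate(names):
            call = rec.samples[name]
            gt = call.get("GT") or (None,)
            for slot, allele in enumerate(gt[:2]):
                row[j, slot] = MISSING if allele is None else allele
            if "DP" in call and call["DP"] is not None:
                dp_row[j] = call["DP"]
                any_dp = True
            if "GQ" in call and call["GQ"] is not None:
                gq_row[j] = call["GQ"]
                any_gq = True
        site_rows.append((rec.chrom, pos0, rec.ref, alts[0]))
        gts.append(row)
        dps.append(dp_row)
        gqs.append(gq_row)
    vf.close()

    callable_intervals = {}
    for chrom, poss in covered.items():
        arr = np.asarray(sorted(poss), dtype=np.int64)
        callable_intervals[chrom] = iv.merge(np.stack([arr, arr + 1], axis=1))

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt"])
    alleles = (np.stack(gts, axis=0) if gts
               else np.zeros((0, len(names), 2), dtype=np.int8))
    return GenotypeMatrix(
        samples=samples, sites=sites, alleles=alleles,
        chrom_class=chrom_class, contig_lengths=contig_lengths,
        callable_intervals=callable_intervals,
        depth=np.stack(dps, axis=0) if (gts and any_dp) else None,
        gq=np.stack(gqs, axis=0) if (gts and any_gq) else None,
    )


# -- small text tables -------------------------------------------------------

def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    samples.reset_index().rename(columns={"index": "sample"}).to_csv(
        path, sep="\t", index=False)


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("sample")


def read_bed(path) -> dict:
    """BED -> {chrom: (n,2) interval array} (0-based half-open, as BED)."""
    out = {}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    for chrom, grp in df.groupby("chrom"):
        out[str(chrom)] = iv.merge(grp[["start", "end"]].to_numpy())
    return out


def write_bed(regions: pd.DataFrame, path) -> None:
    regions[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_sweepfinder_grid(path) -> pd.DataFrame:
    """Two-column (location, LR) SweepFinder2-style output; 1-based positions."""
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}
    loc = cols.get("location", df.columns[0])
    lr = cols.get("lr", df.columns[1])
    return pd.DataFrame({"pos": df[loc].astype(float).astype(np.int64) - 1,
                         "clr": df[lr].astype(float)})


def read_trajectory(path) -> pd.DataFrame:
    """TSV with columns time_years, ne."""
    df = pd.read_csv(path, sep="\t")
    return df[["time_years", "ne"]].astype(float)


def read_frequency_table(path) -> pd.DataFrame:
    """TSV with columns chrom, pos (1-based), p1, p2, p3."""
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"].astype(np.int64) - 1
    return df
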