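import numpy as np
import pandas as pd
import pytest
from Bio.Data import CodonTable

from fastz import coding
from fastz.coding import (CodingSequence, GeneSubstitutionCounts,
                          aggregate_dn_ds, build_sfs, classify_degeneracy,
                          pi_n_pi_s)


def aa_of(codon):
    table = CodonTable.unambiguous_dna_by_id[1]
    return "*" if codon in table.stop_codons else table.forward_table[codon]


def brute_force_degeneracy(seq):
    """Independent per-site enumeration of all three substitutions."""
    out = []
    for ci in range(len(seq) // 3):
        codon = seq[3 * ci:3 * ci + 3]
        for k in range(3):
            nonsyn = sum(aa_of(codon[:k] + b + codon[k + 1:]) != aa_of(codon)
                         for b in "ACGT" if b != codon[k])
            out.append("zero-fold" if nonsyn == 3 else
                       "four-fold" if nonsyn == 0 else "other")
    return out


def test_codon_table_properties():
    # third base of glycine GGN is four-fold; second bases are all zero-fold
    tab = classify_degeneracy([CodingSequence("g", "c", np.arange(6), "GGAGGT")])
    assert list(tab[tab["codon_pos"] == 2]["degeneracy"]) == ["four-fold"] * 2
    rng = np.random.default_rng(0)
    while True:
        seq = "ATG" + "".join(rng.choice(list("ACGT"), size=27))
        if not any(aa_of(seq[i:i + 3]) == "*" for i in range(0, 27, 3)):
            break
    tab = classify_degeneracy([CodingSequence("g", "c", np.arange(len(seq)), seq)])
    second = tab[tab["codon_pos"] == 1]
    assert len(second) == 10
    assert (second["degeneracy"] == "zero-fold").all()


def test_random_gene_matches_substitution_enumeration_oracle():
    rng = np.random.default_rng(1)
    # random 30-codon gene without internal stops
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=90))
        codons = [seq[i:i + 3] for i in range(0, 90, 3)]
        if not any(aa_of(c) == "*" for c in codons[:-1]):
            break
    tab = classify_degeneracy([CodingSequence("g", "c", np.arange(90), seq)])
    assert list(tab["degeneracy"]) == brute_force_degeneracy(seq)


def test_internal_stop_gene_is_skipped():
    with pytest.warns(UserWarning, match="internal stop"):
        tab = classify_degeneracy([
            CodingSequence("bad", "c", np.arange(9), "ATGTAAAAA"),
            CodingSequence("ok", "c", np.arange(9) + 100, "ATGAAACCC"),
        ])
    assert set(tab["gene"]) == {"ok"}


def _five_gene_toy(make_matrix):
    """Hand-built dataset: 5 genes, known zero-/four-fold diversity."""
    rng = np.random.default_rng(6)
    genes = []
    offset = 0
    for g in range(5):
        seq = "ATG" + "GGA" * 4 + "AAA" * 4 + "TGG" * 2  # mixed degeneracy
        genes.append(CodingSequence(f"g{g}", "c", np.arange(len(seq)) + offset, seq))
        offset += 100
    deg = classify_degeneracy(genes)
    # SNPs at a subset of classified positions, alternating frequency
    snp_rows = deg.iloc[::4]
    freqs = [0.25 if i % 2 else 0.5 for i in range(len(snp_rows))]
    gt = []
    for p in freqs:
        n_alt = int(round(p * 8))
        flat = [1] * n_alt + [0] * (8 - n_alt)
        gt.append([[flat[2 * j], flat[2 * j + 1]] for j in range(4)])
    m = make_matrix(gt, pops=["P1"] * 4, sexes=["M"] * 4,
                    chroms=["c"] * len(snp_rows), pos=list(snp_rows["pos"]),
                    ref=["A"] * len(snp_rows), alt=["T"] * len(snp_rows),
                    contig_lengths={"c": offset})
    return m, deg


def test_pi_n_pi_s_matches_two_pass_hand_computation(make_matrix):
    m, deg = _five_gene_toy(make_matrix)
    got = pi_n_pi_s(m, deg, gc_conservative_only=True, n_boot=0)

    # independent two-pass oracle over explicit site lists
    p = m.alt_freq()
    var = {(m.sites.at[i, "chrom"], m.sites.at[i, "pos"]): 2 * p[i] * (1 - p[i])
           for i in range(m.n_sites) if 0 < p[i] < 1}
    sums = {"zero-fold": 0.0, "four-fold": 0.0}
    counts = {"zero-fold": 0, "four-fold": 0}
    for _, row in deg.iterrows():
        cls = row["degeneracy"]
        if cls not in sums:
            continue
        counts[cls] += 1
        sums[cls] += var.get((row["chrom"], row["pos"]), 0.0)
    want = (sums["zero-fold"] / counts["zero-fold"]) / (sums["four-fold"] / counts["four-fold"])
    assert got.value == pytest.approx(want, rel=1e-12)


def test_pi_n_pi_s_degenerate_cases(make_matrix):
    m, deg = _five_gene_toy(make_matrix)
    # keep variation only at four-fold sites -> ratio 0
    four = set(map(tuple, deg.loc[deg.degeneracy == "four-fold", ["chrom", "pos"]].to_numpy()))
    keep = [i for i in range(m.n_sites)
            if (m.sites.at[i, "chrom"], m.sites.at[i, "pos"]) in four]
    m4 = m.subset_sites(np.array(keep))
    assert pi_n_pi_s(m4, deg, n_boot=0).value == 0.0
    # no four-fold variation -> undefined
    zero = set(map(tuple, deg.loc[deg.degeneracy == "zero-fold", ["chrom", "pos"]].to_numpy()))
    keep = [i for i in range(m.n_sites)
            if (m.sites.at[i, "chrom"], m.sites.at[i, "pos"]) in zero]
    with pytest.raises(ValueError, match="four-fold"):
        pi_n_pi_s(m.subset_sites(np.array(keep)), deg, n_boot=0)


def test_dn_ds_weighting_rules():
    # all substitutions W-to-W with f_AT = 0.5: weighted count doubles
    g = GeneSubstitutionCounts("g", nonsyn_ss=0, nonsyn_ww=4, syn_ss=0, syn_ww=8,
                               l_nonsyn=100, l_syn=50, f_gc=0.5)
    res = aggregate_dn_ds([g], n_boot=0)
    assert res.value == pytest.approx((8 / 100) / (16 / 50), rel=1e-12)
    # symmetric counts with f_gc = 0.5: weights cancel against unweighted ratio
    g2 = GeneSubstitutionCounts("g2", 3, 3, 6, 6, l_nonsyn=120, l_syn=40, f_gc=0.5)
    res2 = aggregate_dn_ds([g2], n_boot=0)
    assert res2.value == pytest.approx((6 / 120) / (12 / 40), rel=1e-12)


def test_dn_ds_three_gene_manual_oracle_and_scale_invariance():
    genes = [
        GeneSubstitutionCounts("a", 2, 1, 5, 3, l_nonsyn=300, l_syn=100, f_gc=0.4),
        GeneSubstitutionCounts("b", 0, 2, 1, 6, l_nonsyn=150, l_syn=50, f_gc=0.6),
        GeneSubstitutionCounts("c", 1, 1, 2, 2, l_nonsyn=90, l_syn=30, f_gc=0.5),
    ]
    # spreadsheet-style manual computation
    l_n, l_s = 300 + 150 + 90, 100 + 50 + 30
    tot = sum(g.l_nonsyn + g.l_syn for g in genes)
    f_gc = sum((g.l_nonsyn + g.l_syn) * g.f_gc for g in genes) / tot
    f_at = 1 - f_gc
    dn = (3 / f_gc + 4 / f_at) / l_n
    ds = (8 / f_gc + 11 / f_at) / l_s
    res = aggregate_dn_ds(genes, n_boot=0)
    assert res.value == pytest.approx(dn / ds, rel=1e-12)
    scaled = [GeneSubstitutionCounts(g.gene, 7 * g.nonsyn_ss, 7 * g.nonsyn_ww,
                                     7 * g.syn_ss, 7 * g.syn_ww, g.l_nonsyn,
                                     g.l_syn, g.f_gc) for g in genes]
    assert aggregate_dn_ds(scaled, n_boot=0).value == pytest.approx(res.value, rel=1e-12)


def test_dn_ds_rejects_degenerate_gc_fraction():
    bad = GeneSubstitutionCounts("x", nonsyn_ss=2, nonsyn_ww=0, syn_ss=1,
                                 syn_ww=0, l_nonsyn=10, l_syn=5, f_gc=0.0)
    with pytest.raises(ValueError, match="GC fraction"):
        aggregate_dn_ds([bad], n_boot=0)


def test_sfs_counting(make_matrix):
    """SFS mass: monomorphic classified sites fill bin 0; a site with derived
    count k increments bin k; totals equal the classified site count."""
    seq = "ATG" + "GGA" * 3 + "TGG"
    gene = CodingSequence("g", "c", np.arange(len(seq)), seq)
    deg = classify_degeneracy([gene])
    four = deg[deg["degeneracy"] == "four-fold"]["pos"].tolist()
    # one variant at a four-fold site with derived (alt) count 3 of 8
    gt = [[[1, 1], [1, 0], [0, 0], [0, 0]]]
    m = make_matrix(gt, pops=["P1"] * 4, sexes=["M"] * 4, chroms=["c"],
                    pos=[four[0]], ref=["A"], alt=["T"],
                    contig_lengths={"c": len(seq)})
    calls = pd.DataFrame({"chrom": ["c"], "pos": [four[0]], "ancestral": ["A"],
                          "ancestral_is_ref": [True], "status": ["polarized"],
                          "n_support": [2]})
    sfs = build_sfs(m, calls, deg, n_alleles=8)
    assert sfs["four-fold"][3] == 1
    assert sfs["four-fold"].sum() == len(four)
    assert sfs["zero-fold"][0] == (deg["degeneracy"] == "zero-fold").sum()
    assert sfs["zero-fold"].sum() == (deg["degeneracy"] == "zero-fold").sum()


def test_sfs_write_layout(tmp_path):
    sfs = {"zero-fold": np.array([5.0, 1.0, 0.0]),
           "four-fold": np.array([4.0, 0.0, 2.0])}
    path = tmp_path / "sfs.txt"
    coding.write_sfs(sfs, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "2"
    assert lines[1].split() == ["5", "1", "0"]
    assert lines[2].split() == ["4", "0", "2"]


def test_gff_cds_ingest(tmp_path):
    fasta = tmp_path / "g.fa"
    # gene: two CDS exons on the plus strand spelling ATG GGA TGG
    fasta.write_text(">c1\n" + "TTATGGG" + "ATGGTT" + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("\n".join([
        "##gff-version 3",
        "c1\tsrc\tgene\t3\t11\t.\t+\t.\tID=gene1",
        "c1\tsrc\tmRNA\t3\t11\t.\t+\t.\tID=t1;Parent=gene1",
        "c1\tsrc\tCDS\t3\t7\t.\t+\t0\tID=c;Parent=t1",
        "c1\tsrc\tCDS\t8\t11\t.\t+\t0\tID=c;Parent=t1",
    ]) + "\n")
    cds = coding.read_cds_from_gff(gff, fasta)
    assert len(cds) == 1
    assert cds[0].seq == "ATGGGATGG"
    assert cds[0].positions.tolist() == list(range(2, 11))
    tab = classify_degeneracy(cds)
    # third base of the glycine codon GGA (genomic position 7) is four-fold
    assert tab.loc[tab["pos"] == 7, "degeneracy"].iloc[0] == "four-fold"
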