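import numpy as np
import pytest

from fastz.core import ABSENT, AUTOSOME, MISSING, ZCHROM
from fastz.filtering import FilterConfig, filter_genotypes, filter_sites


def _two_class_matrix(make_matrix, genotypes, depth, gq, pops, sexes):
    n = len(genotypes)
    half = n // 2
    chroms = ["a"] * half + ["z"] * (n - half)
    return make_matrix(genotypes, pops=pops, sexes=sexes, chroms=chroms,
                       pos=list(range(half)) + list(range(n - half)),
                       chrom_class={"a": AUTOSOME, "z": ZCHROM},
                       contig_lengths={"a": 1000, "z": 1000},
                       callable_intervals={"a": np.array([[0, 1000]]),
                                           "z": np.array([[0, 1000]])},
                       depth=depth, gq=gq)


@pytest.mark.parametrize("chrom_class,sex,depth,gq,expect_missing", [
    (AUTOSOME, "M", 4, 99, True),     # depth below 5x fails
    (AUTOSOME, "M", 5, 99, False),    # 5x is kept (removal is strictly below)
    (AUTOSOME, "M", 201, 99, True),   # above 200x fails
    (AUTOSOME, "M", 30, 30, True),    # GQ must be strictly above threshold
    (AUTOSOME, "M", 30, 31, False),
    (ZCHROM, "F", 30, 20, False),     # female Z threshold is GQ > 15
    (ZCHROM, "F", 30, 15, True),
    (ZCHROM, "M", 30, 20, True),      # male Z threshold stays GQ > 30
])
def test_genotype_filter_thresholds(make_matrix, chrom_class, sex, depth, gq,
                                    expect_missing):
    gt = [[[0, ABSENT if (sex == "F" and chrom_class == ZCHROM) else 1]]]
    m = make_matrix(gt, pops=["P1"], sexes=[sex],
                    chroms=["c"], pos=[0], chrom_class={"c": chrom_class},
                    contig_lengths={"c": 10}, depth=[[depth]], gq=[[gq]])
    out = filter_genotypes(m, FilterConfig())
    assert (out.alleles[0, 0, 0] == MISSING) == expect_missing
    # absent hemizygous slots never turn into missing calls
    if sex == "F" and chrom_class == ZCHROM:
        assert out.alleles[0, 0, 1] == ABSENT


def test_site_filter_removes_female_het_z_site(make_matrix):
    gt = [[[0, 1], [0, 0]]]  # sample 0 is a heterozygous female
    m = make_matrix(gt, pops=["P1", "P1"], sexes=["F", "M"], chroms=["z"],
                    pos=[5], chrom_class={"z": ZCHROM}, contig_lengths={"z": 100},
                    callable_intervals={"z": np.array([[0, 100]])})
    out, ledger = filter_sites(m, FilterConfig())
    assert out.n_sites == 0
    assert ledger.L(ZCHROM) == 99


def test_site_filter_missingness_rule(make_matrix):
    # 2 of 10 genotypes missing in P1 (20 % > 10 %) -> site removed
    gt = [[[MISSING, MISSING]] * 2 + [[0, 1]] * 8]
    m = make_matrix(gt, pops=["P1"] * 10, sexes=["M"] * 10,
                    callable_intervals={"chr1": np.array([[0, 10]])},
                    contig_lengths={"chr1": 10})
    out, _ = filter_sites(m, FilterConfig())
    assert out.n_sites == 0
    # exactly 10 % missing is tolerated (rule is "more than 10 %")
    gt = [[[MISSING, MISSING]] + [[0, 1]] * 9]
    m = make_matrix(gt, pops=["P1"] * 10, sexes=["M"] * 10,
                    callable_intervals={"chr1": np.array([[0, 10]])},
                    contig_lengths={"chr1": 10})
    out, _ = filter_sites(m, FilterConfig())
    assert out.n_sites == 1


def _random_toy(make_matrix, seed, n_sites=100):
    rng = np.random.default_rng(seed)
    pops = ["P1"] * 4 + ["P2"] * 4
    sexes = ["M", "F"] * 4
    half = n_sites // 2
    gt = rng.integers(0, 2, size=(n_sites, 8, 2)).astype(np.int8)
    miss = rng.random((n_sites, 8)) < 0.1
    gt[miss] = MISSING
    # hemizygous females on z
    female = np.array([s == "F" for s in sexes])
    gt[half:, female, 1] = ABSENT
    depth = rng.integers(0, 40, size=(n_sites, 8))
    gq = rng.integers(0, 60, size=(n_sites, 8))
    repeat = np.array([[10, 20]])
    m = make_matrix(gt, pops=pops, sexes=sexes,
                    chroms=["a"] * half + ["z"] * (n_sites - half),
                    pos=list(range(half)) + list(range(n_sites - half)),
                    chrom_class={"a": AUTOSOME, "z": ZCHROM},
                    contig_lengths={"a": half, "z": n_sites - half},
                    callable_intervals={"a": np.array([[0, half]]),
                                        "z": np.array([[0, n_sites - half]])},
                    depth=depth, gq=gq)
    cfg = FilterConfig(repeat_mask={"z": repeat})
    return m, cfg


def brute_force_survivors(m, cfg):
    """Site-by-site reapplication of every rule with plain loops."""
    survivors = []
    female = (m.samples["sex"] == "F").to_numpy()
    for i in range(m.n_sites):
        chrom = m.sites.at[i, "chrom"]
        on_z = m.chrom_class[chrom] == ZCHROM
        calls = []
        for j in range(m.n_samples):
            pair = []
            for slot in range(2):
                a = m.alleles[i, j, slot]
                if a == ABSENT:
                    pair.append(ABSENT)
                    continue
                thr = (cfg.gq_z_female if on_z and female[j]
                       else cfg.gq_z_male if on_z else cfg.gq_autosome)
                bad = (a == MISSING or m.depth[i, j] < cfg.min_depth
                       or m.depth[i, j] > cfg.max_depth or m.gq[i, j] <= thr)
                pair.append(MISSING if bad else a)
            calls.append(pair)
        # female heterozygosity on Z
        if on_z and any(female[j] and calls[j][0] >= 0 and calls[j][1] >= 0
                        and calls[j][0] != calls[j][1] for j in range(m.n_samples)):
            continue
        # per-population missingness
        drop = False
        for pop in m.samples["population"].unique():
            idx = [j for j in range(m.n_samples)
                   if m.samples["population"].iloc[j] == pop]
            n_missing = sum(all(a < 0 for a in calls[j]) for j in idx)
            if n_missing / len(idx) > cfg.max_missing_fraction:
                drop = True
        if drop:
            continue
        # repeat overlap
        pos = m.sites.at[i, "pos"]
        in_repeat = any(s <= pos < e for s, e in cfg.repeat_mask.get(chrom, []))
        if in_repeat:
            continue
        survivors.append((chrom, pos))
    return survivors


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_full_filter_matches_per_site_oracle(make_matrix, seed):
    m, cfg = _random_toy(make_matrix, seed)
    filtered, ledger = filter_sites(filter_genotypes(m, cfg), cfg)
    got = list(zip(filtered.sites["chrom"], filtered.sites["pos"]))
    assert got == brute_force_survivors(m, cfg)


def test_filtering_is_idempotent(make_matrix):
    m, cfg = _random_toy(make_matrix, 99)
    once = filter_genotypes(m, cfg)
    assert np.array_equal(filter_genotypes(once, cfg).alleles, once.alleles)
    sites1, ledger1 = filter_sites(once, cfg)
    sites2, ledger2 = filter_sites(sites1, cfg)
    assert sites1.sites.equals(sites2.sites)
    assert ledger1.counts == ledger2.counts


def test_tightening_thresholds_never_grows_ledger(make_matrix):
    m, base = _random_toy(make_matrix, 7)
    loose = filter_sites(filter_genotypes(m, base), base)[1]
    for tight in (FilterConfig(min_depth=10, repeat_mask=base.repeat_mask),
                  FilterConfig(gq_autosome=45, repeat_mask=base.repeat_mask),
                  FilterConfig(max_missing_fraction=0.0, repeat_mask=base.repeat_mask)):
        led = filter_sites(filter_genotypes(m, tight), tight)[1]
        for cls in (AUTOSOME, ZCHROM):
            assert led.L(cls) <= loose.L(cls)


def test_ledger_conserves_site_counts(make_matrix):
    m, cfg = _random_toy(make_matrix, 21)
    g = filter_genotypes(m, cfg)
    filtered, ledger = filter_sites(g, cfg)
    removed = ledger.report.set_index("rule")["sites"]
    assert removed.sum() == m.n_sites  # removed + retained partitions the input
    assert removed["retained"] == filtered.n_sites


def test_missing_sex_label_rejected_on_z(make_matrix):
    m, cfg = _random_toy(make_matrix, 3)
    m.samples.loc[m.samples.index[0], "sex"] = "?"
    with pytest.raises(ValueError, match="sex label"):
        filter_genotypes(m, cfg)
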