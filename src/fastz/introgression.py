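"""Patterson's D, block-jackknife inference, windowed f_d and the
recombination-rate regression.

D is computed from derived-allele frequencies p1, p2, p3 in the three
ingroup populations of a ((P1, P2), P3, O) quartet:

    D = [sum (1-p1) p2 p3 - sum p1 (1-p2) p3] / [sum (1-p1) p2 p3 + sum p1 (1-p2) p3]

with sums over polarized sites taken before the ratio. Standard errors use a
delete-one block jackknife over physical 200-kb tiles. The window-scale
introgression fraction f_d divides the D numerator by its value with the
higher-frequency of P2/P3 substituted for both (the maximal-admixture
donor), which bounds the statistic to [0, 1] where positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .polarize import derived_allele_frequency  # noqa: F401  (re-export convenience)


@dataclass
class FreqQuartet:
    """Per-site derived allele frequencies for (P1, P2, P3)."""

    chrom: np.ndarray
    pos: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray

    def __post_init__(self):
        n = len(self.pos)
        for name in ("chrom", "p1", "p2", "p3"):
            if len(getattr(self, name)) != n:
                raise ValueError("quartet arrays must have equal length")
        for name in ("p1", "p2", "p3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom)

    def complete(self) -> "FreqQuartet":
        """Drop sites with a missing frequency in any population (listwise)."""
        ok = ~(np.isnan(self.p1) | np.isnan(self.p2) | np.isnan(self.p3))
        return FreqQuartet(self.chrom[ok], self.pos[ok],
                           self.p1[ok], self.p2[ok], self.p3[ok])

    @classmethod
    def from_matrix(cls, matrix, calls, pop1, pop2, pop3) -> "FreqQuartet":
        """Build from a genotype matrix and a polarization-call table."""
        freqs = [derived_allele_frequency(matrix, calls,
                                          matrix.sample_indices(population=p))
                 for p in (pop1, pop2, pop3)]
        return cls(matrix.sites["chrom"].to_numpy(), matrix.sites["pos"].to_numpy(),
                   *freqs).complete()


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    p_value: float
    n_blocks: int
    block_size: int
    chrom_class: str | None = None


def _abba_baba(p1, p2, p3):
    abba = (1 - p1) * p2 * p3
    baba = p1 * (1 - p2) * p3
    return abba, baba


def patterson_d(quartet: FreqQuartet) -> float:
    """Frequency-based D; sums over sites taken before the ratio."""
    q = quartet.complete()
    abba, baba = _abba_baba(q.p1, q.p2, q.p3)
    den = abba.sum() + baba.sum()
    if den == 0:
        raise ValueError("D undefined: ABBA + BABA sums to zero")
    return float((abba.sum() - baba.sum()) / den)


def block_jackknife(quartet: FreqQuartet, block_size: int = 200_000,
                    chrom_class: str | None = None) -> DStatResult:
    """Delete-one 200-kb-block jackknife for D.

    Blocks are physical tiles per chromosome; blocks contributing nothing to
    the denominator are dropped from n. With zero jackknife variance the
    z-score is reported as NaN (degenerate).
    """
    q = quartet.complete()
    abba, baba = _abba_baba(q.p1, q.p2, q.p3)
    block = pd.MultiIndex.from_arrays([q.chrom, q.pos // block_size])
    df = pd.DataFrame({"abba": abba, "baba": baba}, index=block) \
        .groupby(level=[0, 1]).sum()
    df = df[(df["abba"] + df["baba"]) > 0]
    n = len(df)
    if n < 2:
        raise ValueError("block jackknife requires at least two non-empty blocks")
    tot_a, tot_b = df["abba"].sum(), df["baba"].sum()
    d = (tot_a - tot_b) / (tot_a + tot_b)
    loo_a = tot_a - df["abba"].to_numpy()
    loo_b = tot_b - df["baba"].to_numpy()
    theta = (loo_a - loo_b) / (loo_a + loo_b)
    se = float(np.sqrt((n - 1) / n * np.sum((theta - theta.mean()) ** 2)))
    z = d / se if se > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return DStatResult(d=float(d), se=se, z=float(z), p_value=float(p),
                       n_blocks=n, block_size=block_size, chrom_class=chrom_class)


def fd_windows(quartet: FreqQuartet, window: int = 200_000,
               min_sites: int = 10, contig_lengths: dict | None = None) -> pd.DataFrame:
    """Windowed f_d = S(P1,P2,P3) / S(P1,P_D,P_D), P_D = max(p2, p3) per site.

    Windows with fewer than `min_sites` polarized sites, a negative numerator
    (not biologically meaningful) or a zero denominator are reported missing.
    """
    q = quartet.complete()
    abba, baba = _abba_baba(q.p1, q.p2, q.p3)
    num = abba - baba
    pd_ = np.maximum(q.p2, q.p3)
    dena, denb = _abba_baba(q.p1, pd_, pd_)
    den = dena - denb

    block = pd.MultiIndex.from_arrays([q.chrom, q.pos // window])
    agg = pd.DataFrame({"num": num, "den": den, "n": 1}, index=block) \
        .groupby(level=[0, 1]).sum()

    rows = []
    if contig_lengths:
        keys = [(c, w) for c in sorted(contig_lengths)
                for w in range(int(np.ceil(contig_lengths[c] / window)))]
    else:
        keys = list(agg.index)
    for c, w in keys:
        if (c, w) in agg.index:
            s_num, s_den, n = agg.loc[(c, w)]
        else:
            s_num, s_den, n = 0.0, 0.0, 0
        if n < min_sites or s_num < 0 or s_den == 0:
            fd = np.nan
        elif s_num == 0:
            fd = 0.0
        else:
            fd = s_num / s_den
        rows.append((c, int(w) * window, (int(w) + 1) * window, fd, int(n)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fd", "n_sites"])


def call_fd_outliers(table: pd.DataFrame, sg_window: int = 5, sg_order: int = 3,
                     z_threshold: float = -2.0) -> pd.DataFrame:
    """Smooth f_d per chromosome, z-transform with genome-wide moments of the
    smoothed values, and flag windows with z <= threshold."""
    from scipy.signal import savgol_filter

    tab = table.reset_index(drop=True).copy()
    vals = tab["fd"].to_numpy(dtype=float)
    smoothed = np.full(len(tab), np.nan)
    for chrom, grp in tab.groupby("chrom"):
        idx = grp.index[np.isfinite(vals[grp.index])]
        if len(idx) < sg_window:
            import warnings
            warnings.warn(f"chromosome {chrom}: fewer than {sg_window} valid "
                          "f_d windows; skipped")
            continue
        smoothed[idx] = savgol_filter(vals[idx], sg_window, sg_order, mode="interp")
    ok = np.isfinite(smoothed)
    z = np.full(len(tab), np.nan)
    if ok.sum() >= 2:
        mu, sd = smoothed[ok].mean(), smoothed[ok].std()
        # guard the degenerate constant case against smoothing round-off
        z[ok] = (smoothed[ok] - mu) / sd if sd > 1e-9 * max(1.0, abs(mu)) else 0.0
    tab["smoothed"] = smoothed
    tab["z"] = z
    tab["outlier"] = np.isfinite(z) & (z <= z_threshold)
    return tab


def fd_recombination_regression(fd, recomb_rate):
    """OLS of f_d on recombination rate: returns (R^2, slope, p-value)."""
    fd = np.asarray(fd, dtype=float)
    rr = np.asarray(recomb_rate, dtype=float)
    ok = np.isfinite(fd) & np.isfinite(rr)
    if ok.sum() < 3:
        raise ValueError("regression needs at least three paired windows")
    if np.std(rr[ok]) == 0:
        raise ValueError("zero variance in recombination rate; fit undefined")
    res = stats.linregress(rr[ok], fd[ok])
    return float(res.rvalue**2), float(res.slope), float(res.pvalue)
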