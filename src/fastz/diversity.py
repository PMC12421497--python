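"""Nucleotide diversity, Z:A effective-size ratios and trajectory ratios.

Diversity is the paper-style per-site heterozygosity pi = sum(2 p q) / L over
variable sites, with L the callable-site denominator from the filter ledger
(no sample-size correction). Z:A ratios divide the Z-side quantity by the
male-bias factor alpha (default 1.1) before the ratio, compensating the
elevated Z mutation rate expected under male-biased mutation.

Confidence intervals come from a percentile bootstrap. Two resampling units
are provided: the variable-site bootstrap (sites resampled with replacement,
L fixed), and a per-locus block bootstrap for data composed of independent
loci, where whole loci are the exchangeable unit and the site-level scheme
would understate genealogical variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .core import GenotypeMatrix, CallableLedger

STRONG = frozenset("GC")
WEAK = frozenset("AT")


@dataclass
class PiEstimate:
    pi: float
    s: int
    L: int
    chrom_class: str
    site_filter: str = "all"
    ci: tuple | None = None
    contributions: np.ndarray | None = None
    locus: np.ndarray | None = None

    def __post_init__(self):
        if self.ci is not None and not (self.ci[0] <= self.pi <= self.ci[1]):
            raise ValueError("CI does not bracket the point estimate")


@dataclass
class ZARatio:
    ratio: float
    alpha: float
    method: str
    ci: tuple | None = None


def gc_conservative(ref, alt) -> np.ndarray:
    """True where both alleles are strong (G/C) or both weak (A/T)."""
    ref = np.char.upper(np.asarray(ref, dtype="U1"))
    alt = np.char.upper(np.asarray(alt, dtype="U1"))
    valid = np.isin(ref, list("ACGT")) & np.isin(alt, list("ACGT"))
    if not valid.all():
        raise ValueError("non-ACGT allele in GC-conservative classification")
    strong = np.isin(ref, list(STRONG)) & np.isin(alt, list(STRONG))
    weak = np.isin(ref, list(WEAK)) & np.isin(alt, list(WEAK))
    return strong | weak


def build_linked_selection_mask(exons, cnes, flank: int = 1000,
                                min_cne_size: int = 100) -> np.ndarray:
    """Union of exons and CNEs (>= min size) extended by `flank` bp each side."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    exons = iv.as_interval_array(exons)
    cnes = iv.as_interval_array(cnes)
    if len(cnes):
        cnes = cnes[(cnes[:, 1] - cnes[:, 0]) >= min_cne_size]
    parts = [a for a in (exons, cnes) if len(a)]
    if not parts:
        return np.zeros((0, 2), dtype=np.int64)
    return iv.expand(np.concatenate(parts, axis=0), flank)


def compute_pi(matrix: GenotypeMatrix, ledger: CallableLedger, chrom_class: str,
               population=None, site_filter: str = "all",
               mask: dict | None = None) -> PiEstimate:
    """Per-site nucleotide diversity for one chromosome class and population.

    site_filter: 'all' | 'gc' (GC-conservative SNPs only, same L) |
    'masked' (sites outside `mask`, L reduced by the masked callable span).
    """
    if site_filter not in ("all", "gc", "masked"):
        raise ValueError(f"unknown site_filter {site_filter!r}")
    cls = matrix.site_class()
    sel = cls == chrom_class
    if site_filter == "gc":
        sel &= gc_conservative(matrix.sites["ref"], matrix.sites["alt"])
    L = ledger.L(chrom_class)
    if site_filter == "masked":
        if mask is None:
            raise ValueError("site_filter='masked' requires a mask")
        pos = matrix.sites["pos"].to_numpy()
        chroms = matrix.sites["chrom"].to_numpy()
        L = 0
        for chrom, ivs in matrix.callable_intervals.items():
            if matrix.chrom_class[chrom] != chrom_class:
                continue
            m = mask.get(chrom)
            kept = iv.subtract(ivs, m) if m is not None and len(m) else iv.merge(ivs)
            L += iv.total_span(kept)
            on = chroms == chrom
            if m is not None and len(m):
                sel[on] &= ~iv.contains(m, pos[on])
    if L <= 0:
        raise ValueError("callable-site denominator L must be positive")

    idx = None if population is None else matrix.sample_indices(population=population)
    p = matrix.alt_freq(idx)
    variable = sel & ~np.isnan(p) & (p > 0) & (p < 1)
    contrib = 2 * p[variable] * (1 - p[variable])
    locus = (matrix.sites["locus"].to_numpy()[variable]
             if "locus" in matrix.sites.columns else None)
    return PiEstimate(pi=float(contrib.sum() / L), s=int(variable.sum()), L=int(L),
                      chrom_class=chrom_class, site_filter=site_filter,
                      contributions=contrib, locus=locus)


def bootstrap_ci(contributions, L: int, n_reps: int = 1000, seed=None,
                 alpha_level: float = 0.05) -> tuple:
    """Percentile CI of sum(contributions)/L, resampling variable sites."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    c = np.asarray(contributions, dtype=float)
    if c.size < 1:
        raise ValueError("at least one variable site required")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, c.size, size=(n_reps, c.size))
    stats = c[draws].sum(axis=1) / L
    lo, hi = np.quantile(stats, [alpha_level / 2, 1 - alpha_level / 2])
    return float(lo), float(hi)


def z_a_ratio(pi_z: PiEstimate, pi_a: PiEstimate, alpha: float = 1.1,
              method: str | None = None) -> ZARatio:
    """Male-bias-corrected diversity ratio (pi_Z / alpha) / pi_A."""
    if pi_z.site_filter != pi_a.site_filter:
        raise ValueError("Z and autosomal estimates use different site filters")
    if pi_a.pi == 0:
        raise ValueError("autosomal pi is zero; ratio undefined")
    return ZARatio(ratio=(pi_z.pi / alpha) / pi_a.pi, alpha=alpha,
                   method=method or {"all": "All sites", "gc": "GC cons",
                                     "masked": "No LS"}[pi_z.site_filter])


def z_a_ratio_site_ci(pi_z: PiEstimate, pi_a: PiEstimate, alpha: float = 1.1,
                      n_reps: int = 1000, seed=None) -> tuple:
    """Percentile CI for the corrected ratio, resampling variable sites
    independently within each chromosome class."""
    rng = np.random.default_rng(seed)
    cz, ca = pi_z.contributions, pi_a.contributions
    dz = rng.integers(0, cz.size, size=(n_reps, cz.size))
    da = rng.integers(0, ca.size, size=(n_reps, ca.size))
    ratios = (cz[dz].sum(axis=1) / pi_z.L / alpha) / (ca[da].sum(axis=1) / pi_a.L)
    lo, hi = np.quantile(ratios, [0.025, 0.975])
    return float(lo), float(hi)


def z_a_ratio_locus_ci(pi_z: PiEstimate, pi_a: PiEstimate, n_loci_z: int,
                       n_loci_a: int, alpha: float = 1.1, n_reps: int = 1000,
                       seed=None) -> tuple:
    """Percentile CI resampling whole loci with replacement (block bootstrap).

    For data built of independent equal-length loci, the locus is the
    exchangeable unit: sites within a locus share one genealogy, so
    site-level resampling is anti-conservative. Requires the estimates to
    carry per-site locus labels.
    """
    if pi_z.locus is None or pi_a.locus is None:
        raise ValueError("locus labels required for the block bootstrap")
    rng = np.random.default_rng(seed)

    def per_locus(est, n_loci):
        lab = np.asarray([l[1] if isinstance(l, tuple) else l for l in est.locus])
        return np.bincount(lab, weights=est.contributions, minlength=n_loci)

    sums_z = per_locus(pi_z, n_loci_z)
    sums_a = per_locus(pi_a, n_loci_a)
    dz = rng.integers(0, n_loci_z, size=(n_reps, n_loci_z))
    da = rng.integers(0, n_loci_a, size=(n_reps, n_loci_a))
    ratios = ((sums_z[dz].sum(axis=1) / pi_z.L / alpha)
              / (sums_a[da].sum(axis=1) / pi_a.L))
    lo, hi = np.quantile(ratios, [0.025, 0.975])
    return float(lo), float(hi)


def heterozygosity_bias_factor(n_alleles: float) -> float:
    """Finite-sample expectation factor of sum(2 p q): E = (1 - 1/n) theta.

    The per-site heterozygosity statistic omits the n/(n-1) correction, which
    is negligible for population-scale panels but matters for small simulated
    samples -- and differs between autosomes and Z because hemizygous females
    contribute one allele. Parameter-recovery estimators divide it out.
    """
    if n_alleles < 2:
        raise ValueError("need at least two alleles")
    return 1.0 - 1.0 / n_alleles


def recover_z_a_ratio(pi_z: PiEstimate, pi_a: PiEstimate, n_alleles_z: int,
                      n_alleles_a: int, n_loci_z: int, n_loci_a: int,
                      alpha: float = 1.1, n_reps: int = 1000, seed=None):
    """Estimate the simulated Z:A effective-size ratio rho with CI.

    Applies the male-bias correction (divide Z by alpha) and removes the
    finite-sample heterozygosity factors, then attaches a per-locus block
    bootstrap percentile CI (scaled by the same deterministic factors).
    Returns (rho_hat, (lo, hi)).
    """
    correction = (heterozygosity_bias_factor(n_alleles_a)
                  / heterozygosity_bias_factor(n_alleles_z))
    point = z_a_ratio(pi_z, pi_a, alpha=alpha).ratio * correction
    lo, hi = z_a_ratio_locus_ci(pi_z, pi_a, n_loci_z, n_loci_a,
                                alpha=alpha, n_reps=n_reps, seed=seed)
    return point, (lo * correction, hi * correction)


# -- demographic trajectories ------------------------------------------------

def resample_trajectory(traj: pd.DataFrame, step: float = 1000.0,
                        t_max: float = 1e6) -> np.ndarray:
    """Piecewise-constant resampling of (time_years, ne) change points onto a
    discrete grid from the most recent time up to `t_max`."""
    t = traj["time_years"].to_numpy(dtype=float)
    ne = traj["ne"].to_numpy(dtype=float)
    if np.any(ne <= 0):
        raise ValueError("Ne must be strictly positive")
    if np.any(np.diff(t) < 0):
        raise ValueError("trajectory times must be ascending")
    grid = np.arange(0.0, t_max, step)
    idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, len(t) - 1)
    return ne[idx]


def harmonic_mean(values) -> float:
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("harmonic mean requires strictly positive values")
    return float(len(v) / np.sum(1.0 / v))


def harmonic_mean_ne_ratio(traj_z: pd.DataFrame, traj_a: pd.DataFrame,
                           alpha: float = 1.1, step: float = 1000.0,
                           t_max: float = 1e6) -> ZARatio:
    """(H_Z / alpha) / H_A of harmonic-mean Ne over the common time grid."""
    hz = harmonic_mean(resample_trajectory(traj_z, step, t_max))
    ha = harmonic_mean(resample_trajectory(traj_a, step, t_max))
    return ZARatio(ratio=(hz / alpha) / ha, alpha=alpha, method="PSMC")


def rescale_psmc(times_scaled, lambdas, theta0: float, bin_size: int = 100,
                 mu: float = 4.6e-9, generation_time: float = 2.0) -> pd.DataFrame:
    """Convert scaled PSMC output to (time_years, ne).

    N0 = theta0 / (4 mu bin_size); Ne_k = N0 * lambda_k;
    t_k[years] = 2 N0 * t_scaled_k * generation_time.
    """
    n0 = theta0 / (4 * mu * bin_size)
    t = 2 * n0 * np.asarray(times_scaled, dtype=float) * generation_time
    ne = n0 * np.asarray(lambdas, dtype=float)
    return pd.DataFrame({"time_years": t, "ne": ne})


# -- breeding-sex-number expectations ----------------------------------------

def breeding_ne(n_males: float, n_females: float) -> tuple:
    """(Ne_Z, Ne_A) under unequal numbers of breeding males and females.

    Standard expressions: Ne_A = 4 Nm Nf / (Nm + Nf) and
    Ne_Z = 9 Nm Nf / (4 Nm + 2 Nf) for a ZW system (males carry two Z).
    """
    if n_males <= 0 or n_females <= 0:
        raise ValueError("breeding numbers must be positive")
    ne_a = 4 * n_males * n_females / (n_males + n_females)
    ne_z = 9 * n_males * n_females / (4 * n_males + 2 * n_females)
    return ne_z, ne_a


def breeding_z_a_ratio(n_males: float, n_females: float) -> float:
    ne_z, ne_a = breeding_ne(n_males, n_females)
    return ne_z / ne_a


def breeding_z_a_ratio_limits() -> tuple:
    """Analytic limits of the Z:A Ne ratio under extreme sex-biased breeding
    numbers, evaluated symbolically: (male-biased limit, female-biased limit)."""
    import sympy

    r = sympy.symbols("r", positive=True)  # r = Nm / Nf
    ratio = (9 * r / (4 * r + 2)) / (4 * r / (r + 1))
    male_extreme = sympy.limit(ratio, r, sympy.oo)
    female_extreme = sympy.limit(ratio, r, 0)
    return float(male_extreme), float(female_extreme)
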