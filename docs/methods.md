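# Methods

This note documents the models and procedures implemented in `fastz`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## The synthetic data generator

`fastz.simulate` produces genotype data with the structure of a two-sister-
pair study design: populations P1–P4 with topology ((P1,P2),(P3,P4)) plus an
outgroup OUT, autosomal and Z-linked loci, and known truth.

**Model.** Each locus is an independent neutral coalescent genealogy
(msprime, no within-locus recombination) of fixed length (default 2 kb),
placed on a synthetic contig at a configurable stride (default 200 kb, so
one locus falls in each analysis window/jackknife block). Mutations follow a
binary model; reference (ancestral) and alternate (derived) nucleotides are
assigned per site from a seeded RNG with all six unordered base pairs equally
likely, so one third of SNPs are GC-conservative by construction. Sites
rendered invariant by recurrent mutation are dropped.

**Z linkage.** Z-linked inheritance is represented by its coalescent
consequences: Z loci evolve in a population of effective size ρ·N<sub>e</sub>
(ρ = `z_a_ratio`, default 0.75, the neutral expectation with equal breeding
sex numbers) with mutation rate α·μ (α = `male_bias`, default 1.1, the
male-bias factor the analysis corrects for; μ = 4.6 × 10⁻⁹ per site per
generation). Each female contributes one sampled lineage on Z (hemizygous;
the second genotype slot is a structural-absence sentinel), each male two.
Sex labels default to alternating M/F within each population.

**Demography.** Default diploid N<sub>e</sub> = 10⁵ per population; split
times 100 k (P1/P2), 150 k (P3/P4), 300 k (cross-pair) and 600 k (outgroup)
generations — a configuration resembling a young flycatcher-like radiation
with a clean outgroup. Optional gene flow is continuous unidirectional
P3 → P2 (backwards-time lineage movement P2 → P3) between the present and the
P1/P2 split; a separate rate may be set for Z loci to emulate reduced
effective migration on the sex chromosome. Generation time (2 y) enters only
when rescaling demographic trajectories; the simulator itself works in
generations.

**What is not emulated.** Linked selection, background selection, gBGC,
within-locus recombination, sequencing error and mapping artifacts. Passing
tests therefore validate the estimators and their sampling properties under
neutrality — not robustness to those confounders, which is exactly why the
empirical pipeline carries GC-conservative and linked-selection-masked
variants of the diversity ratios.

## Filtering

Genotype level: calls with depth < 5× or > 200× are removed, as are calls
with GQ ≤ 30 (autosomes and Z males) or GQ ≤ 15 (hemizygous Z females, which
carry half the reads). Bounds are exclusive as stated ("below 5×",
"GQ > 30"): depth exactly 5 survives, GQ exactly 30 does not. Site level,
applied after genotype filters: (a) Z sites with any remaining heterozygous
female genotype are removed entirely (the heterozygous call is biologically
impossible and implicates the site, not just the call); (b) sites with more
than 10% missing genotypes in any population are removed, a hemizygous
female call counting as one observation; (c) repeat-masked sites are
removed. The callable-site ledger subtracts repeat spans *and every dropped
variant position* from the callable intervals, which makes filtering
idempotent including its denominators.

## Polarization

A site's ancestral allele is the allele fixed in at least two of three
groups (outgroup; sister pair 1; sister pair 2). "Fixed" requires ≥
`min_calls` (default 1, matching a single-individual outgroup) non-missing
alleles and no alternative allele. Sites monomorphic across all calls are
trivially polarized; a two-vs-one fixed disagreement goes to the majority.
Sites with missing data in one group but fixed agreement in the other two
are polarized — the rule as stated allows it. The ancestralized reference
masks non-genotyped positions and unpolarizable variable positions with `N`
and substitutes the ancestral allele elsewhere.

Note that the two-of-three rule structurally discards sites segregating in
both ingroup pairs (no two groups can then be fixed). For four-taxon
introgression tests those are exactly the informative sites, so the
D/f<sub>d</sub> path uses `polarize_by_outgroup`: derived state defined by
outgroup fixation alone, mirroring the use of dedicated outgroup individuals
in the empirical ABBA-BABA setting.

One caveat a property test documents: the fraction of polarized sites is
*not* monotone in missingness for this rule (masking a minority allele can
turn a polymorphic group into a fixed one). Monotonicity holds, and is
tested, for internally monomorphic groups and for the `min_calls` threshold.

## Diversity and Z:A ratios

π = Σ 2p<sub>i</sub>q<sub>i</sub> / L over variable sites, frequencies from
non-missing alleles, L from the ledger, with no sample-size correction —
the field's population-scale convention. Three site filters: all SNPs,
GC-conservative SNPs (same L), and linked-selection-masked (exons and CNEs
≥ 100 bp, each ± 1 kb, removed from both the SNP set and L). The Z:A ratio
divides the Z-side estimate by α = 1.1 before the ratio.

**Bootstraps.** The reporting bootstrap resamples variable sites with
replacement (percentile CI, 1000 replicates, L fixed), as the empirical
analysis describes. For parameter recovery on locus-structured simulated
data this scheme is anti-conservative — sites within a locus share one
genealogy, and the randomness of the segregating-site count is not resampled
— so the recovery suite uses a per-locus block bootstrap (loci are the
exchangeable unit). Both are exposed; the choice is documented at the call
sites.

**Finite-sample factor.** E[Σ 2p̂q̂] = (1 − 1/n)·θ for n sampled alleles.
With ~hundreds of genomes this is negligible, but in small simulated samples
n differs between autosomes (2S alleles) and Z (2M + F), biasing the raw
ratio low by (1 − 1/n_Z)/(1 − 1/n_A). `recover_z_a_ratio` divides this known
deterministic factor out (point estimate and CI alike); the plain reporting
path leaves the statistic exactly as conventionally defined.

**Trajectories.** Harmonic-mean N<sub>e</sub> ratios take piecewise-constant
trajectories resampled on a 1000-year grid from the present to 1 Mya;
H = n / Σ(1/N<sub>t</sub>); the ratio is (H_Z/α)/H_A. A helper rescales
scaled PSMC-style output via N₀ = θ₀/(4μs), t[years] = 2N₀·t_scaled·g with
g = 2 y. The analytic breeding-sex expressions N<sub>eA</sub> = 4N<sub>m</sub>N<sub>f</sub>/(N<sub>m</sub>+N<sub>f</sub>),
N<sub>eZ</sub> = 9N<sub>m</sub>N<sub>f</sub>/(4N<sub>m</sub>+2N<sub>f</sub>) give the ratio limits 9/16 (extreme male bias)
and 9/8 (extreme female bias), evaluated symbolically with sympy.

## Coding selection

Degeneracy is a pure codon-table property (standard nuclear code): zero-fold
if all three substitutions are nonsynonymous, four-fold if none is. Genes
with internal stops are flagged and skipped; trailing partial codons are
trimmed; for overlapping transcripts the caller supplies one (longest)
transcript per gene. π<sub>N</sub>/π<sub>S</sub> is the ratio of per-site π
at zero-fold vs four-fold sites, GC-conservative SNPs only by default, with
CIs from resampling genes (100 replicates). Pooled d<sub>N</sub>/d<sub>S</sub>
weights each GC-conservative substitution class by the fraction of sites
able to undergo it — S-to-S counts divided by f<sub>GC</sub>, W-to-W by
f<sub>AT</sub>, then summed (the multiplicative alternative sits behind a
flag, since the verbal description admits both readings). The unfolded SFS
per degeneracy class counts derived alleles at polarized sites, monomorphic
classified sites filling bin 0, with optional hypergeometric down-projection
for heterogeneous sample sizes; output is a plain whitespace spectrum file
for DFE-style downstream tools (the DFE fitting itself is out of scope).

## Differentiation and sweeps

Weir–Cockerham (1984) variance components a, b, c per site, window estimate
Σa/Σ(a+b+c) in 200-kb tiles from position 0 (trailing partial windows kept
and flagged). Negative window estimates are reported as computed. On
hemizygous Z sites the per-population sample size is half the non-missing
allele count (possibly fractional) and heterozygosity comes from diploid
individuals only. Peak calling: per-chromosome z-transform, Savitzky–Golay
smoothing (window 5, order 3 — not specified in the source analysis;
configurable and recorded in output), flag smoothed z > 2. The SG edge
handling is scipy's `mode="interp"`, i.e. a truncated-window polynomial
refit. PBS uses the same z-score flagging; F<sub>ST</sub> ≥ 1 is dropped
(NaN) by default or capped on request.

Sweep post-processing takes an external CLR grid (e.g. SweepFinder2 output),
thresholds at CLR > 46.25, merges runs of consecutive significant grid
positions (no gap allowance by default; `max_gap` available), removes
single-position regions and regions with fewer than 1 significant site per
kb of span, and marks 200-kb windows overlapped by retained regions.

## Introgression

D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA) with ABBA = (1−p₁)p₂p₃ and BABA =
p₁(1−p₂)p₃ over outgroup-polarized sites; sites missing a frequency in any
population are dropped listwise; sums are taken before the ratio. Inference
is a delete-one block jackknife over physical 200-kb tiles (blocks with no
informative sites dropped from n): SE = √(((n−1)/n)·Σ(θ₍ᵢ₎ − θ̄)²),
z = D/SE, two-sided normal p. f<sub>d</sub> divides the windowed D numerator
by its value with the higher of p₂/p₃ substituted for both ("maximal
donor"); windows below `min_sites` (default 10, unspecified in the source),
with negative numerator, or zero denominator are reported missing, and a
zero numerator gives 0. Outlier windows: per-chromosome SG smoothing, then a
z-transform on the *genome-wide* moments of the smoothed values, flagging
z ≤ −2. The recombination regression is plain OLS of window f<sub>d</sub> on
window recombination rate (R², slope, two-sided slope p).

## Enrichment

Fixed difference: both species fixed, for different alleles; shared
polymorphism: segregating in both; statuses partition typed sites.
Functional categories follow the precedence zero-fold/four-fold > UTR > CNE
> intron > intergenic (the source does not state one; recorded in output).
Densities are fixed differences per category-callable site. The 2×2
Z-vs-autosome tests report the sample cross-product odds ratio (a·d)/(b·c)
— the convention matching the published tables — with a two-sided Fisher
exact p (sum of hypergeometric probabilities ≤ the observed table's); a zero
off-diagonal cell yields an infinite OR with a one-sided p.

## Problem sizes and numerical choices

The test and acceptance runs use 200 independent 2-kb loci per chromosome
class and 4 samples per population (6 Z alleles, 8 autosomal alleles per
population), 1000 bootstrap replicates, and 20 replicate simulations per
recovery condition — sizes at which the coalescent SD of the π-ratio is
≈ 5–8% and a desk machine completes the whole suite in about a minute.
Savitzky–Golay parameters, thresholds (z > 2, z ≤ −2, CLR > 46.25), window
and block sizes (200 kb), α (1.1) and μ (4.6 × 10⁻⁹) are all configurable
with the defaults above. Degenerate cases are explicit errors or flagged
values rather than silent NaN: zero callable L, zero four-fold diversity,
single jackknife block, zero-variance predictors, constant series in the
z-transform (guarded against smoothing round-off).

## Known limitations

* The generator's neutral independent-locus model cannot exhibit the
  linked-selection or gBGC signals whose *corrections* the pipeline
  implements; those paths are validated for mechanics (masking, subsetting)
  rather than effect recovery.
* WC84 with fractional hemizygous sample sizes is a pragmatic convention,
  not a derived estimator; comparisons mixing Z and autosomal windows should
  treat small-sample Z F<sub>ST</sub> with care.
* The site-resampling bootstrap understates uncertainty whenever sites are
  genealogically clustered; prefer the block bootstrap on locus- or
  window-structured data.
* PSMC-style trajectory inference, CLR computation, alignment and DFE
  fitting are deliberately external: this package post-processes their
  outputs.
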