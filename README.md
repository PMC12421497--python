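# fastz

Sex-aware population genomics of **fast-Z** and **large-Z** effects in ZW
systems (birds and other female-heterogametic taxa), built as a tested,
reusable pipeline with a coalescent data generator so every stage can be
exercised without external downloads.

## The scientific problem

In birds the Z chromosome differentiates faster than the autosomes (the
*fast-Z* effect) and contributes disproportionately to reproductive isolation
(the *large-Z* effect). Both patterns are routinely read as evidence of
positive selection, but they also follow directly from genetic drift: the Z
has a smaller effective population size than the autosomes — N<sub>eZ</sub>/N<sub>eA</sub> = 3/4
under equal breeding sex numbers, and anywhere in [9/16, 9/8] under
sex-biased reproductive variance — which accelerates lineage sorting and
reduces introgression chromosome-wide without any barrier loci.
Disentangling drift from adaptation requires jointly measuring:

* the **Z:A ratio of N<sub>e</sub>**, from diversity
  (π = Σ<sub>i</sub> 2p<sub>i</sub>q<sub>i</sub> / L over variable sites, with
  L callable sites) on all SNPs, on GC-conservative SNPs (immune to GC-biased
  gene conversion), and after masking genes/CNEs ± 1 kb (linked selection),
  plus harmonic-mean N<sub>e</sub> from demographic trajectories — all divided
  by α = 1.1 on the Z side to correct for male-biased mutation;
* **differentiation scans**: Weir–Cockerham F<sub>ST</sub> and the population
  branch statistic PBS = (T<sub>AB</sub> + T<sub>AC</sub> − T<sub>BC</sub>)/2,
  T = −ln(1 − F<sub>ST</sub>), in 200-kb windows with smoothed-Z peak calling,
  and post-processing of composite-likelihood sweep scans (CLR > 46.25,
  merged regions, single-position and <1 site/kb regions removed);
* **selection on coding sequence**: zero-fold/four-fold degeneracy,
  π<sub>N</sub>/π<sub>S</sub> and GC-weighted d<sub>N</sub>/d<sub>S</sub> on
  GC-conservative sites, unfolded SFS export;
* **introgression**: Patterson's D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA) from
  derived-allele frequencies with a 200-kb block jackknife, windowed
  f<sub>d</sub> with outlier calling (smoothed z ≤ −2), and the
  recombination-rate regression;
* **Z-vs-autosome enrichment**: Fisher exact tests on flagged/unflagged
  200-kb window counts.

All of it is sex-aware: hemizygous females carry a single Z allele, genotype
filters use sex-specific GQ thresholds on the Z, and sites with heterozygous
female Z calls are removed as artifacts.

## Worked example

```python
from fastz import SimConfig, simulate_dataset, compute_pi, CallableLedger
from fastz.core import AUTOSOME, ZCHROM
from fastz.diversity import recover_z_a_ratio
from fastz.polarize import polarize_by_outgroup
from fastz.introgression import FreqQuartet, block_jackknife

cfg = SimConfig(n_autosomal_loci=200, n_z_loci=200, z_a_ratio=0.75,
                migration_rate=2e-5, seed=42)
matrix, truth = simulate_dataset(cfg)

ledger = CallableLedger(counts={AUTOSOME: 200 * cfg.locus_length,
                                ZCHROM: 200 * cfg.locus_length})
pi_z = compute_pi(matrix, ledger, ZCHROM, population="P1")
pi_a = compute_pi(matrix, ledger, AUTOSOME, population="P1")
rho, (lo, hi) = recover_z_a_ratio(pi_z, pi_a, n_alleles_z=6, n_alleles_a=8,
                                  n_loci_z=200, n_loci_a=200, seed=1)

auto = matrix.subset_sites(matrix.site_class() == AUTOSOME)
calls = polarize_by_outgroup(auto, "OUT")
res = block_jackknife(FreqQuartet.from_matrix(auto, calls, "P1", "P2", "P3"))
```

This prints (via the obvious `print` calls):

```
18192 variant sites across 20 samples
pi_A = 0.00157, pi_Z = 0.00123
estimated Z:A Ne ratio = 0.748 (95% CI 0.674-0.832)
Patterson's D = 0.834 +/- 0.035 (z = 24.1, 198 blocks)
```

The simulated Z:A ratio (0.75) is recovered by the α-corrected π ratio, and
the strong simulated P3→P2 gene flow produces a large positive D with a
block-jackknife z far above 2; with `migration_rate=0` the same pipeline
returns D within a few SE of zero.

A command-line interface mirrors the library:

```bash
fastz simulate --config sim.yaml --out-prefix run1
fastz filter --vcf run1.vcf --metadata run1.samples.tsv --out filtered.vcf
fastz zaratio --vcf run1.vcf --metadata run1.samples.tsv --population P1 --out ratio.tsv
fastz dstat --freqs freqs.tsv --out d.tsv
fastz enrich --table window_counts.tsv --out enrichment.tsv
```

Subcommands: `simulate filter polarize pi zaratio fst pbs sweeps dstat fd
classify enrich`. Every run writes a provenance JSON (parameter hash, seed,
version) next to its output.

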