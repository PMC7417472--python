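# Methods

`bulkscan` implements a bulked-segregant QTL-seq analysis for biparental
crosses, together with a synthetic data generator that emulates the study
design the pipeline targets: a rice F2 population of 983 lines segregating
for salt tolerance at the bud burst stage, phenotyped as the relative shoot
length (RSL = shoot length under salt / shoot length under control),
bulked into 40 extreme-tolerant (T-pool) and 40 extreme-sensitive (S-pool)
lines, and pool-sequenced at ~27.6× mean depth.

## The genome-scan model

At every biallelic SNP with pooled read counts the scan computes:

* **SNP-index** per pool: the fraction of reads carrying the non-reference
  allele, `alt / (ref + alt)`.
* **ΔSNP-index**: `SNP-index(S) − SNP-index(T)`. Genome-wide this is ≈ 0;
  near a causal locus the extreme bulks are enriched for opposite alleles
  and Δ deviates toward ±1. The sign convention is configurable
  (`t_minus_s`) because the convention in the literature depends on which
  bulk is named first; the convention used is recorded in the scan output.
* **Euclidean distance (ED)** between the pools' four-base read-frequency
  vectors, `ED = sqrt(Σ_b (f_b,T − f_b,S)²)` over b ∈ {A, C, G, T}. For a
  biallelic site the two vectors differ in exactly two coordinates by the
  same amount, so `ED = √2 · |SNP-index(T) − SNP-index(S)|`; ED is 0 for
  identical pools and √2 for pools fixed for different alleles.

### Smoothing

Raw per-SNP statistics are dominated by binomial read noise. Both
statistics are smoothed with a tricube-weighted sliding window (default
half-width 1 Mb, evaluated at every SNP, never spanning chromosomes).
Following the ED literature, raw ED is raised to a power (default 4) before
smoothing to suppress background noise. Windows holding fewer than
`min_window_snps` (default 10) markers yield no fitted value. The kernel
window was chosen over loess because it is transparent and exactly
reproducible by a brute-force kernel sum, which the tests exploit.

### ΔSNP-index significance

Depth-conditional null bounds are simulated per unique (depth_T, depth_S)
pair: each pool's allele frequency is drawn as Binomial(2·bulk_size, ½)
(1:2:1 F2 segregation among the pooled lines), read counts are then
binomial at the observed depths, and the 95th/99th bounds of |Δ| are
extracted (default 10,000 simulations). Two numerical details:

* |Δ| lives on a coarse grid (multiples of 1/depth). An interpolated
  quantile combined with the strict `|Δ| > bound` rule is systematically
  conservative — measured exceedance dropped to ~0.03 at depth 30 — so the
  bound is taken at the atom of the simulated null whose exceedance
  probability is closest to the nominal level. Measured null exceedance is
  then 0.04–0.06.
* Bounds are forced monotone non-increasing in total depth across the
  simulated grid, so Monte-Carlo jitter cannot make a deeper marker easier
  to call than a shallower one.

### ED significance

Two thresholding rules are provided:

* `ed_threshold` — the genome-empirical rule: median + k·scale (default
  k = 3) of all fitted values. The scale is the normal-consistent MAD
  (1.4826 × median absolute deviation); on Gaussian fitted values it equals
  the SD, so k = 3 keeps its usual meaning, while staying calibrated when a
  minority of the genome carries linked signal. The root-mean-square
  deviation about the median is available as `scale="sd"`.
* `ed_null_threshold` (the pipeline default) — a parametric-bootstrap
  genome-wide threshold: no-QTL genomes are simulated with the observed
  marker map, the observed per-SNP depths, F2 gametes recombining under the
  same map function, and random bulks of the same size; each is pushed
  through the identical powering/smoothing, and the threshold is the 95th
  percentile of the per-genome maximum fitted ED (20 genomes by default).
  Exceeding it controls the genome-wide false-positive rate at ~5%.

The bootstrap rule exists because any location+scale rule computed from the
observed genome fails when linked signal spans most of it. On a
one-chromosome genome carrying a strong QTL, essentially every marker is
linked to the causal locus under extreme selection, the "background" no
longer exists, and the empirical threshold climbs above the genome maximum.
The bootstrap threshold is computed under the no-QTL null and is immune to
this; in simulation it produced no false ED region in 10 no-QTL genomes
while recovering the planted QTL in every probed run. The empirical rule
remains appropriate (and cheaper) for multi-chromosome genomes where most
of the genome is unlinked.

### Region calling and intersection

Markers pass where |fitted Δ| exceeds their simulated bound (95% by
default) or fitted ED exceeds the threshold. Maximal runs of consecutive
passing SNPs become regions; runs separated by ≤ 500 kb are merged. Δ
region ends are rounded outward to a 10-kb grid because the statistic is
window-based; ED regions keep raw SNP positions. Region size in Mb is
(end − start)/10⁶ rounded to 2 decimals, matching the convention of the
published region tables this reproduces. The candidate interval of a
two-method analysis is every positive-length pairwise overlap between the Δ
and ED region sets.

## The synthetic generator

The generator emulates the study design, not sequencing reads:

* **Cross**: F1 gametes are simulated marker-to-marker per chromosome;
  adjacent-marker recombination fractions come from physical distance via
  the Haldane map function at 4 cM/Mb (rice-typical, configurable).
  Genotypes are the sum of two gametes, coded 0/1/2 tolerant-parent
  alleles, hence 1:2:1 segregation and realistic linkage decay. One marker
  is placed exactly at the configured QTL position.
* **Phenotype**: `y = μ + a·(g − 1) + d·a·[g = 1] + e`, Gaussian residuals
  (sd 0.10), dominance d = 0 by default. The additive effect is sized from
  the requested PVE: since var(g − 1) = ½ under 1:2:1,
  `a = σ_e · sqrt(2·pve/(1 − pve))`; default PVE 0.249 matches the
  QTL effect the design targets. μ = 0.75 puts values on a plausible
  relative-trait scale (the scan is invariant to μ and to the overall
  variance scale).
* **Bulks**: the `bulk_size` largest and smallest phenotypes (stable
  (value, line-id) sort; boundary ties warn, since composition is then
  order-determined).
* **Depths**: per SNP and pool, total depth ~ Poisson(27.6) truncated at
  ≥ 1 (a constant-depth model is available for calibration studies); the
  alt count is Binomial(depth, pooled allele frequency).
* **DEG tables**: planted causal genes receive FDR < 0.05 and a fixed log2
  ratio in designated contrasts; all other cells draw uniform null FDRs.

All randomness flows from one seed through named, independently spawned
per-stage streams, so any stage can be re-run in isolation and identical
(config, seed) pairs give byte-identical outputs.

What the generator does **not** emulate: sequencing error, mapping bias,
duplicated/repetitive regions, variable marker informativeness, multi-QTL
genetics, or the F2:3 family structure (the pooled genotype is taken to be
the sequenced F2 individual's genotype, since leaves of the F2 plants were
the sequenced material in the emulated design). Passing tests therefore
demonstrate the statistical machinery is correct under the stated
generative model, not that real sequencing artefacts are handled.

## Phenotype handling

Relative traits are treatment/control per line; control = 0 leaves the
ratio undefined and the record is excluded with a counted log entry.
Distribution diagnostics use bias-corrected sample skewness and excess
kurtosis; a trait is flagged suitable for QTL analysis when both absolute
values are below 1. Pool comparisons use the two-sided
Wilcoxon–Mann–Whitney test, chosen over a t test because relative root
traits are strongly zero-inflated; phenotyping designs with many lines
stopped by stress produce exactly this pattern.

## Candidate triage

DEG significance is strict FDR < 0.05 (−log10 FDR > 1.3) with direction
from the sign of the log2 ratio; no fold-change cut-off is applied by
default. The four contrast sets partition into 15 disjoint membership
subgroups with percentages of the union. Gene–interval intersection uses
any-overlap (≥ 1 bp, switchable to full containment). Candidates are region
genes significant in ≥ 1 designated within-variety contrast (default
IRvsTIR and WGvsTWG), ranked by minimum FDR across those contrasts to make
the output order deterministic. qRT-PCR fold change is 2^(−ΔΔCt). The
single-marker association test is one-way fixed-effects ANOVA across
genotype classes; constant input returns F = 0, p = 1, and perfect
separation reports p = 0.

## Filters on ingest

Biallelic SNPs only; minimum total depth 7 per pool; per-pool depth capped
at the 99th percentile (repetitive-region proxy); when parental depths are
present, parents must look homozygous for different alleles (≥ 90% of reads
on opposite alleles). Without parent data the scan orients alleles by
reference/alternate with a logged caveat. All filter counts are logged and
recorded in the run manifest.

## Problem sizes used in the shipped analyses

The calibration study uses 10,000 markers (10 chromosomes × 1,000) at
constant depth 30 with 10,000 null simulations. The recovery study uses 20
replicates of the emulated design point: 983 lines, bulks of 40, PVE 0.249,
5,000 markers on one 30-Mb chromosome, mean depth 27.6. The bootstrap ED
threshold uses 20 null genomes per analysis. These sizes reproduce the
design being emulated while keeping a full run on one CPU in minutes.

## Known limitations

* The simulated CI for Δ assumes an F2 design (allele probability ½ per
  pooled chromosome); other cross designs need a different null.
* The ED bootstrap threshold assumes the configured cM/Mb rate describes
  the genome; a strongly wrong rate shifts the null correlation length.
* Region boundaries inherit marker-density resolution; the 10-kb rounding
  of Δ regions is cosmetic, not a confidence statement.
* Published sequencing-scale results that depend on raw-read processing
  (total SNP counts, LOD/PVE from interval mapping, DEG totals) are out of
  scope; the package consumes allele-depth and DEG tables, it does not
  produce them from reads.
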