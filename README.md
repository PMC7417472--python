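# bulkscan

Bulked-segregant QTL-seq analysis for biparental crosses: per-SNP
SNP-index / ΔSNP-index and Euclidean-distance (ED) genome scans over pooled
allele depths, simulation-based significance thresholds, two-method region
intersection, and candidate-gene triage against differential-expression
tables — plus a truth-tagged synthetic generator of F2 populations, extreme
bulks and pooled read counts so the whole pipeline can be exercised and
validated offline.

It is aimed at quantitative geneticists running QTL-seq/BSA-seq experiments
(the motivating design is rice salt tolerance at the bud burst stage: 983
F2 lines, 40+40 extreme bulks selected on relative shoot length, ~27.6×
pooled depth) and at anyone who wants a tested, reproducible reference
implementation of the two standard pooled-scan statistics.

## The statistics

For a SNP with pooled reference/alternate read counts in a tolerant (T) and
sensitive (S) bulk:

* SNP-index = alt / (ref + alt) per pool — the fraction of reads carrying
  the non-reference allele;
* ΔSNP-index = SNP-index(S) − SNP-index(T), ≈ 0 genome-wide and deviating
  toward ±1 near a causal locus;
* ED = sqrt(Σ_b (f_b,T − f_b,S)²) over the four base frequencies, in
  [0, √2] for biallelic sites.

Both statistics are tricube-window smoothed (ED first raised to the 4th
power). |Δ| is tested against depth-conditional null bounds simulated under
1:2:1 F2 segregation plus binomial read sampling; fitted ED is tested
against a genome-wide threshold (parametric-bootstrap null by default, a
robust median + 3·MAD rule as an alternative). Candidate intervals are the
overlaps of the Δ and ED region sets; genes in the interval that are
differentially expressed in designated contrasts (FDR < 0.05) become
candidates. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 4-chromosome F2 study (983 lines, bulks of 40, one QTL of PVE
0.249 in the middle of chr3, 27.6× mean depth) and scan it:

```python
from bulkscan import SimConfig, simulate_dataset, compute_scan
from bulkscan.scan import call_regions, ed_null_threshold, intersect_region_sets

cfg = SimConfig(seed=1, n_chrom=4, n_snps_per_chrom=2000, qtl_chrom="chr3")
ds = simulate_dataset(cfg)
pts = compute_scan(ds.depths, bulk_size=cfg.bulk_size, seed=1)

delta = call_regions(pts, "delta")
ed = call_regions(pts, "ed",
                  threshold=ed_null_threshold(pts, cfg.bulk_size, seed=1))
common = intersect_region_sets(delta, ed)
print("QTL planted at", cfg.qtl_chrom, cfg.qtl_pos_bp)
for r in common:
    print(f"common region {r.chrom}:{r.start_bp}-{r.end_bp} ({r.size_mb} Mb)")
```

prints

```
QTL planted at chr3 15000000
common region chr3:2550000-24290000 (21.74 Mb)
```

Both methods flag only the QTL chromosome — the three unlinked chromosomes
produce no region — and their intersection covers the planted position. The
interval is broad because under extreme-bulk selection a 25%-PVE QTL shifts
allele frequencies detectably across much of its chromosome; narrowing it
is the job of downstream regional mapping, not the genome scan. The same
analysis runs from the shell:

```sh
bulkscan --seed 1 --out-dir out run
```

which writes the depth tables (TSV + VCF), the per-SNP scan table, region
calls (BED + a Method/Chromosome/Start/End/Size-Mb table), candidate and
Venn tables, and a run manifest with record counts. Identical config + seed
reproduce every data file byte for byte.

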