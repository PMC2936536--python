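# sweepscan

A multi-statistic genome scan for recent positive selection in a focal
population contrasted with two reference populations, together with a
forward-time three-population simulator that generates every input the
pipeline consumes.

The scan combines four complementary statistics:

- **LSBL** — per-marker locus-specific branch lengths obtained by
  triangulating pairwise Weir–Cockerham FST estimates across the three
  populations; an elevated focal branch marks focal-specific allele
  frequency change.
- **lnRH** — the log ratio of window-averaged expected heterozygosity
  between the focal and reference population (100 kb windows, 25 kb step);
  strongly negative values mark a focal-specific loss of diversity.
- **Standardized difference of Tajima's D** — a z-score of the per-window
  difference between focal and reference Tajima's D; negative values mark
  a focal-specific excess of rare variants.
- **Long-range haplotype (EHH/REHH) scan** — core haplotypes with longer
  than expected homozygosity given their frequency, judged against a
  per-frequency-bin gamma null with Benjamini–Hochberg FDR control, and
  restricted to cores carrying a high-frequency (> 0.85) derived allele.

Downstream machinery: genome-wide empirical p-values (`(rank − 1)/N`,
autosomes and X ranked separately) with top-5%/1% significance flags;
hypergeometric clustering of significant markers/windows into 1-Mb regions
with Bonferroni correction and candidate-region nomination; per-gene
extreme-statistic ranking against a genome-wide per-gene null (genes plus
50 kb flanks); a one-sided Kolmogorov–Smirnov pathway-enrichment test; and
biallelic copy-number polymorphisms analyzed as ordinary markers, including
single-marker REHH at a CNP boundary.

## Layout

| Module | Role |
| --- | --- |
| `sweepscan.data_model` | Marker/genotype/haplotype/gene containers; VCF, genotype-TSV, BED and sample-map I/O; 95% call-rate filter; autosome/X partition |
| `sweepscan.diversity` | Allele counts, expected heterozygosity, Weir–Cockerham FST, LSBL, region-mean FST |
| `sweepscan.windows` | Sliding-window grid, lnRH, Tajima's D, standardized tracks |
| `sweepscan.empirical` | Empirical ranks, p-values, significance counts/flags |
| `sweepscan.regions` | Hypergeometric 1-Mb region scan, region nomination, interval overlap |
| `sweepscan.genes` | Gene scoring against the per-gene null, pathway K-S test |
| `sweepscan.haplotypes` | Core haplotypes, EHH/REHH, gamma MLE, BH-FDR, whole-genome haplotype scan, CNP boundary REHH |
| `sweepscan.simulate` | Forward-time Wright–Fisher simulator (three populations, optional highland-only sweep), synthetic gene annotation, fixture writer |

## CLI

```bash
# simulate a dataset with a selective sweep in the highland population
sweepscan simulate --seed 1 --selection 0.1 --out-dir fixture/

# run the scan (LSBL, windows, empirical flags, regions, gene ranking)
sweepscan scan --genotypes fixture/haplotypes.vcf \
    --sample-map fixture/sample_map.tsv --genes fixture/genes.bed \
    --focal highland --ref1 lowland --ref2 outgroup --out-dir results/
```

## Notes

- Internal coordinates are 1-based inclusive; BED files are converted on
  read/write. Missing genotypes are sentinel-coded and never imputed.
- Undefined statistics (monomorphic markers, empty windows, S = 0) are NaN
  and excluded from ranking and standardization.
- The haplotype scan requires phased input; the simulator emits phased
  haplotypes directly.
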