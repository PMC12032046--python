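# ilqtl

QTL mapping in introgression libraries phenotyped on high-throughput
platforms — from SNP genotypes to donor-segment calls, from daily
biomass/water time series to thermal-time water-balance traits, through
spatial correction, heritability and BLUPs, to a segment-wise association
scan with LD-based QTL clustering. A first-class synthetic-data generator
reproduces the statistical structure of such a study, so the whole chain is
testable without any external download.

## Who this is for

Quantitative geneticists working with introgression libraries (ILs,
chromosome-segment substitution lines): collections of near-isogenic lines
each carrying one or a few donor-genome segments in a recurrent-parent
background. The motivating design is a maize library of ~69 lines (an early
landrace donor in an elite background) measured for water use, water-use
efficiency (WUE) and growth under well-watered (`ww`) and water-deficit
(`wd`) treatments, with seedling root/shoot dry weights from a paper-roll
assay — the setting in which a *negative* relationship between
root-to-shoot ratio and WUE can be dissected into QTL clusters.

## The analysis

1. **Segments.** Markers coded A (recurrent hom.), B (donor hom.), H, N are
   QC-filtered (monomorphic, unplaced, >10% missing). Maximal runs of
   identical donor scores become introgression segments, labelled by their
   first SNP; identical spans merge into unique segments, and a line
   carries a unique segment when one of its own segments spans it. Pairwise
   segment LD is the two-sided Fisher exact p on carrier 2×2 tables
   (high LD: p < 0.01).
2. **Traits.** Time is measured in thermal days (1 T-day = heat accumulated
   in 24 h at constant 20 °C). Over the evaluation window (stress-target
   day to harvest): biomass accumulation `Δb/Δτ` (g/T-day), daily water use
   `Σw/Δτ` (g/T-day), WUE `100·Δb/Σw` (g/100 g water), specific
   transpiration (g/m²/T-day), plus early vigor (biomass at the 8-leaf
   stage), leaf appearance rate (OLS slope of leaf count on τ), ww/wd
   response ratios, and seedling root/shoot traits.
3. **Correction & genetics.** Outliers by a robust MAD rule; six spatial
   correction methods (none, row/column mixed model, two moving-average
   variants, and the two composites); per trait the method with the highest
   entry-mean broad-sense heritability `h² = σ²_G/(σ²_G + σ²_e/r)` is
   adopted; genotype BLUPs are shrunken line means.
4. **Population statistics.** Pearson correlations with Benjamini–Hochberg
   FDR, PCA on scaled BLUPs, Dunnett many-to-one contrasts against the
   recurrent parent, sequential-SS variance partitioning.
5. **QTL.** Per segment and trait, a pooled t-test of carriers vs
   non-carriers on line entry means, Bonferroni-corrected over the segments
   tested for that trait; stepwise (AIC) multi-segment refinement; QTL
   clusters = LD-connected significant segments associated with ≥2 traits,
   split when linked members have opposite effect signs on a shared trait.

## Worked example

Run the full pipeline on the default synthetic study (69 IL lines + two
parents, 8 replicates × 2 treatments, a planted three-locus QTL scenario):

```bash
ilqtl run --seed 0 --out out/
# pipeline complete: 263 unique segments, 1 QTL clusters; manifest at out/manifest.json
```

`out/qtl_report.csv` then contains (abridged):

```
cluster  chrom            trait    segment  effect  effect_pct  neg_log10_p
     Q1      3       biomass_wd SNP_3_0066   -1.13      -29.60         7.24
     Q1      3       biomass_ww SNP_3_0066   -2.95      -21.23         2.94
     Q1      3           wue_ww SNP_3_0066   -2.38      -40.16         5.02
     Q1      3     water_use_ww SNP_3_0066   90.16       37.88         9.17
```

Read: the donor segment on chromosome 3 tagged by SNP_3_0066 lowers biomass
accumulation by 2.95 g/T-day under ww (−21% of the non-carrier mean) and
lowers WUE, while raising water use — a multi-trait cluster with
internally consistent effect directions, matching the planted scenario.
`out/heritability.csv` lists the six correction methods' h² per trait and
the selected one; `out/correlations_r.csv` shows the planted antagonism as
a negative correlation between seedling root-to-shoot ratio and platform
WUE (≈ −0.3 under ww at the default seed).

The same stages are available as library calls (`ilqtl.run_analysis`,
`ilqtl.segment_scan`, `ilqtl.select_correction`, …) and as the
subcommands `ilqtl simulate`, `ilqtl segments`, `ilqtl traits`,
`ilqtl correct`, `ilqtl stats`, `ilqtl qtl` and `ilqtl run`, each
reading and writing the documented CSV/TSV formats.

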