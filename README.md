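# demescope

Deme-level differentiation and individual autosomal heterozygosity analysis
for conservation genomics.

## What problem this addresses

Small, isolated wildlife populations lose heterozygosity through drift and
inbreeding, but most genomic studies summarise diversity only at the
population level. When local breeding groups ("demes") are not well mixed —
because of rivers, canals, cleared land or simply limited dispersal —
individuals *within* one deme can differ two-fold in heterozygosity, and
population means hide exactly the spatial pattern a manager needs:
*where* are the low-heterozygosity animals accumulating?

`demescope` is a tested pipeline for answering that question from a jointly
genotyped variant file **that retains invariant sites**, plus a sample
metadata table (deme label, coordinates, sex, year). It computes:

- the standard RADseq SNP/sample filtering cascade (per-locus call rate
  overall and within demes, per-sample missingness, minor allele count,
  mean-depth window with the `mean + 4·sqrt(mean)` maximum-depth rule,
  distance thinning), with a per-stage report;
- a kinship screen (robust moment estimators of the kinship coefficient
  *K* and of *K*₀, the probability of sharing no alleles identical by
  descent) and a sex-linkage screen (exact tests of heterozygosity and
  call-rate differences between sexes);
- **per-individual autosomal heterozygosity** H_O = heterozygous retained
  records / all retained records, filtering each individual separately
  (depth window, missing data, spanning-deletion sites) and keeping
  invariant sites in the denominator so estimates are comparable across
  individuals and unbiased by cohort size; multi-allelic records are
  atomized into one biallelic record per alternate allele first;
- per-deme Wright's F_IS (per-site 1 − H_obs/H_exp averaged over loci) and
  a per-sample H_O profile over windows of the size-concatenated
  pseudogenome;
- pairwise Weir–Cockerham **F_ST** (multilocus θ as a ratio of summed
  variance components a, b, c) with locus bootstrap, percentile CIs and
  Bonferroni-corrected significance; private allele counts per deme;
- isolation by distance: Rousset's **â** individual genetic distance
  (â = Σ(Q̂_w − Q̂_ij) / Σ(1 − Q̂_w) over loci) against log great-circle
  distance, tested with one-sided permutation **Mantel** tests at deme,
  region and global scope; genotype PCA;
- **ordinary kriging** of individual H_O: empirical semivariogram, weighted
  exponential fit γ(h) = nugget + psill·(1 − e^(−h/range)), 36-nearest-
  neighbour prediction, and a surface of deviations from the global mean
  H_O in standard-deviation units.

Because the statistical structure of such studies is hard to obtain as open
data, the package includes a first-class **synthetic-data generator**: a
hierarchical Balding–Nichols model (two regions, seven demes by default)
with per-individual inbreeding coefficients, within-deme isolation by
distance, planted sibling/parent-offspring dyads, optional X-linked loci,
negative-binomial depth and missingness — written as standard VCF
(variant *and* invariant records) plus CSV metadata and truth tables, so
every estimator can be validated against known truth.

## Worked example

Run the whole pipeline on the default synthetic cohort (85 individuals in
7 demes, 50,000 sites of which 5,000 are polymorphic):

```bash
demescope run-all --seed 1 --out run/
cat run/summary.txt
```

```
# Individual autosomal heterozygosity summary

Lowest H_O : 1.540e-02 (NW_008, deme NW)
Highest H_O: 3.249e-02 (DW_001, deme DW)

      count    mean     min     max  max_min_ratio
deme
DE       13 0.02506 0.01673  0.0313          1.871
DW       22 0.02558 0.01658 0.03249          1.959
NE        6 0.02201  0.0168 0.02984          1.776
NW       18 0.02498  0.0154  0.0322          2.091
TE        7 0.02617 0.02082 0.02982          1.432
TP       10  0.0227 0.01873 0.03008          1.606
TW        9 0.02346  0.0189 0.03147          1.665

One-way ANOVA across demes: F_6,78 = 0.937, p = 0.473
H_O ~ retained sites: R^2 = 0.001 (slope -2.87e-06)
H_O ~ sampling year: R^2 = 0.003 (slope -0.000229)
```

Reading this: individuals within a deme differ up to 2.1-fold in H_O (the
generator draws inbreeding coefficients F_i uniformly on [0, 0.5], and
expected heterozygosity scales as 1 − F_i), so despite real deme structure
the deme means are statistically indistinguishable (F₆,₇₈ = 0.94) — the
inter-individual spread, not the deme label, carries the signal. H_O is
uncorrelated with the number of retained sites and with sampling year,
confirming the per-individual filtering removes data-quantity artefacts.
The H_O scale (~10⁻²) reflects the synthetic panel's site density; on
whole-genome data with tens of millions of invariant sites the same
estimator lands in the 10⁻³–10⁻⁴ range.

The run directory also contains `fst_pairs.csv` / `fst_matrix.csv`
(within-region θ ≈ 0.05, between-region θ ≈ 0.12 under the default
divergence parameters, all pairs bootstrap-significant), `kinship.csv`
(3,570 dyads for 85 samples, planted siblings flagged), `mantel.csv`
(positive isolation by distance), and `kriged_surface.csv` (x, y,
prediction, variance, z columns).

Each stage is also available separately (`demescope simulate | filter |
het | structure | krige | report`) and as library functions
(`demescope.genofilter`, `demescope.hetpipe`, `demescope.structstats`,
`demescope.spatialhet`).

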