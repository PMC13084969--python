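# Methods

This note documents the models and estimators implemented in `demescope`,
the defaults chosen where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## The synthetic cohort generator (`demescope.simdata`)

The generator emulates a state-wide RADseq survey of a low-dispersal
terrestrial mammal: seven demes in two regions (four northern, three
southern), 85 diploid individuals by default (deme sizes 18, 9, 7, 6, 22,
13, 10), genotyped at 50,000 sites scattered over 200 contigs of
decreasing length (100 kb down to 20 kb), of which 10% are polymorphic in
the ancestral pool and the rest are invariant but genotyped with depth —
the data shape required by the invariant-site heterozygosity estimator.

**Allele frequencies.** Hierarchical Balding–Nichols: for a variable site
with ancestral frequency p ~ U(0.05, 0.95), each region draws
q ~ Beta(p(1−θ_r)/θ_r, (1−p)(1−θ_r)/θ_r) and each deme draws likewise
around its region with θ_d. θ is the expected fixation index of each draw
around its parent; the within-deme coancestry relative to the ancestral
pool is θ_r + (1−θ_r)θ_d, which is what pairwise Weir–Cockerham θ between
demes of different regions estimates (verified by simulation in the test
suite). Defaults θ_r = 0.08, θ_d = 0.05 give between-region θ ≈ 0.12 and
within-region θ ≈ 0.05, the magnitudes typical of strongly structured
small-mammal surveys. Invariant sites (p = 0) propagate unchanged.

**Individuals.** Each individual receives an inbreeding coefficient F_i
drawn uniformly from its deme's interval (default [0, 0.5], making
expected heterozygosity 2p(1−p)(1−F_i) vary two-fold within a deme).
Genotypes are drawn per site with P(het) = 2p(1−p)(1−F_i) and the
homozygote classes receiving p² + F_i p(1−p) and (1−p)² + F_i p(1−p).

**Isolation by distance.** Individuals scatter around deme centroids with
isotropic Gaussian noise (default 8 km s.d.). With `ibd_slope` > 0 the
deme frequency at site l is tilted for individual i as
clip(p + slope·s_l·u_i, 0, 1), where u_i is the standardized longitude of
i within the deme (≈ [−½, ½]) and s_l a random-sign site effect of
magnitude sqrt(p(1−p)). Spatially close individuals therefore share
similar frequencies, which yields a positive within-deme Mantel
correlation between Rousset's â and log distance. The slope is a free
knob — real systems provide no portable calibration for how much
within-deme signal to expect — and defaults to 0.3, enough for the
default cohort to detect global isolation by distance without swamping
the deme-level divergence.

**Relatives, sex linkage, noise.** Planted dyads are generated by
explicit Mendelian transmission from simulated parents (full sibs share
both parents; parent–offspring pairs include the parent itself); members
always share a deme. X-linked loci give males a single allele, reported
as a homozygous diploid call, as standard genotypers do for unphased
hemizygotes. Depth is negative binomial (mean 40, size 8 — RAD depth is
overdispersed; size → ∞ recovers Poisson), genotypes with zero depth or
hit by the independent missingness probability (default 0.05) are
missing, and an optional error rate perturbs called genotypes. Output is
VCF 4.2 (invariant records with `ALT=.`, per-genotype `GT:DP`) plus CSV
metadata and truth tables; identical config + seed reproduces every file
byte-for-byte.

## Filtering cascade (`demescope.genofilter`)

Stage order: first-pass locus call rate (> 0.70) → per-sample missingness
(retain < 0.10, strict) → stricter call rate (> 0.85 overall **and**
> 0.50 within every deme) → minor allele count ≥ 3 → site quality ≥ 30 →
mean-depth window [5, 95] → optional 10 kb greedy thinning. Thinning keeps
the first site per contig and then each site at least the minimum distance
from the last *kept* site (first-kept greedy; unsorted input is an error,
never silently sorted). The maximum-depth rule of thumb
`mean + c·sqrt(mean)` (default c = 4) is provided for choosing the window's
upper edge. Each stage records sites/samples in and out with its
thresholds. The upstream caller's multi-annotation hard filters are
represented by the single site-quality threshold, since the generator
emits one quality scalar per site; the other annotations are internal to
read-level callers and out of scope here.

**Kinship.** For each pair, over biallelic polymorphic loci called in
both samples: K = (N_het,het − 2·N_opposite-hom) / (N_het,i + N_het,j) —
the robust within-pair moment estimator, which needs no external allele
frequencies — and K0 = N_opposite-hom / Σ_l 2p_l²(1−p_l)², the count of
opposite homozygotes normalized by its unrelated-pair expectation,
clamped to [0, 1]. Classification bands: K ≥ 0.354 duplicate-or-self;
K ∈ [0.177, 0.354) parent–offspring if K0 < 0.1 else full-sib;
K ∈ [0.088, 0.177) half-sib; otherwise unrelated. K0 separates
parent–offspring (K0 → 0: every locus shares one allele) from full sibs
(K0 ≥ 0.25). Full sibs whose realized K0 falls below 0.1 are classified
parent–offspring — the two first-degree classes genuinely overlap at
panel sizes of a few thousand SNPs, which is why the screen reports the
raw K/K0 values alongside the label.

**Sex linkage.** Per locus with ≥ 5 called individuals of each sex:
Fisher exact tests on het/non-het × sex (X-linked pattern: significant
and males the less heterozygous sex) and on called/missing × sex
(Y/W-like pattern), Bonferroni-corrected at family-wise 0.05 over
testable loci. Unsexed samples are ignored.

## Individual heterozygosity (`demescope.hetpipe`)

H_O for an individual is n_het / n_retained over that individual's own
retained records. Retention drops, per individual only: missing calls,
sites whose ALT includes the spanning-deletion symbol `*`, and calls with
depth < 15 or > 95 (depth exactly at a bound is retained — the rule
removes "less than" and "more than"). Multi-allelic sites are atomized
first: a site with k alternate alleles contributes k records, and a
genotype made of two *different* alternate alleles is heterozygous in
both derived records. Invariant sites count in the denominator, which is
what makes H_O insensitive to how many other samples were genotyped and
to each sample's own missingness. Loci flagged by the sex-linkage screen
are excluded by default so the estimate stays autosomal. Atomized records
are counted at the record level (not collapsed back to physical sites),
matching the atomize-then-count order of the filtering convention.

**F_IS.** Per deme, per biallelic locus with ≥ 2 called members and
within-deme H_exp = 2p̂(1−p̂) > 0: F_locus = 1 − H_obs/H_exp; the deme
value is the unweighted mean over loci. The uncorrected per-site form is
the default (it mirrors the per-site coefficient most callers emit) and
carries a known O(1/2n) downward bias; `sample_size_correction=True`
multiplies H_exp by 2n/(2n−1) and removes most of it. Whether to average
per-site coefficients or pool counts was an open choice; the unweighted
per-site mean was chosen and both the correction and the minimum-call
threshold are exposed.

**Window profile.** Contigs are ordered by descending length and
concatenated into a pseudogenome; windows (default 200 kb) tile it, and
each sample's H_O is computed per window with the same per-individual
filters. Windows with fewer than 50 retained records for a sample
(configurable) are reported absent (NaN), not zero, to avoid unstable
ratios.

## Differentiation and isolation by distance (`demescope.structstats`)

**Weir–Cockerham θ.** Per biallelic locus with ≥ 2 called individuals in
each deme, the a / b / c variance components for unequal sample sizes are
computed from per-deme sample sizes, allele frequencies and heterozygote
proportions; multilocus θ = Σa / Σ(a+b+c) (ratio of sums, not mean of
per-locus ratios — the tests pin this distinction on a two-locus
fixture). Sample sizes are per-locus counts of called genotypes.
Significance: loci resampled with replacement (default 10,000 bootstrap
replicates), percentile 95% CI, one-sided p = fraction of bootstrap
θ* ≤ 0 (θ < 0 is estimation noise, so only positive differentiation is
tested), flagged at per-test α = 0.01 / n_pairs (21 pairs for 7 demes).

**Private alleles.** An allele (reference included) is private to a deme
if observed there and in no other deme, over called genotypes.

**Rousset's â.** â_ij = Σ_l (Q̂_w,l − Q̂_ij,l) / Σ_l (1 − Q̂_w,l) over loci
called in both individuals: Q̂_w,l is the probability of identity of the
two genes within an individual (1 for homozygotes, 0 for heterozygotes)
averaged over the analysis scope, Q̂_ij,l the identity probability for one
gene from each individual (x_i x_j + (1−x_i)(1−x_j) with x the
half-dosage). The scope of Q̂_w follows the analysis (deme members for
within-deme tests, the whole cohort globally) and is recorded with the
result. A sample with no within-individual diversity makes the
denominator zero; the estimator then returns an explicit degenerate flag
rather than a number. The identity-probability (allele-identity) form is
implemented; allele-size weighting variants are not.

**Mantel.** r is the Pearson correlation of upper-triangle entries;
the null distribution comes from simultaneous row/column permutations of
one matrix; the test is one-sided for positive association with
p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1), ties counted in the tail.
Geographic distance is great-circle (haversine, mean Earth radius
6371.0088 km) and enters as the natural log; coincident pairs are
excluded and reported. Natural rather than base-10 log is the default
(the choice only rescales r's covariate linearly; a base-10 flag would
change nothing in the test statistic's p-value).

**PCA.** Centered 0/1/2 alt-dosage matrix of polymorphic biallelic loci,
missing genotypes imputed by the locus mean (the conventional choice),
SVD scores and eigenvalue shares.

## Kriging of heterozygosity (`demescope.spatialhet`)

Empirical semivariogram γ̂(bin) = Σ(v_i − v_j)²/(2N_bin) over equal-width
distance bins (empty bins absent, not zero); exponential model
γ(h) = nugget + psill(1 − e^(−h/range)) fitted by least squares weighted
by per-bin pair counts, parameters bounded non-negative, deterministic
starting values (nugget 0, psill = max γ̂, range = max lag / 3). A
degenerate fit (psill ≈ 0 or collapsed range) returns a pure-nugget model
with a warning. Prediction is ordinary kriging — weights constrained to
sum to one via a Lagrange multiplier — on the 36 nearest observations per
grid node (capped at n), with covariance C(h) = psill·e^(−h/range) and
the nugget only on the system diagonal, so zero-nugget kriging
interpolates the data exactly (asserted to 1e-8). Coincident observations
are averaged before solving. The grid defaults to the samples' bounding
box padded 10%, 100×100 nodes; distances are haversine km directly on
lon/lat, adequate at deme scale (tens of km ≪ Earth radius) — a
projection hook is left open. The final surface is reported as
z = (prediction − mean H_O)/sd(H_O) with the sample s.d. of the observed
values, i.e. deviation from the global mean in s.d. units. No coastline
masking is applied; a GIS layer can mask the exported grid downstream.
Upstream GIS products do not disclose their variogram fitting, so
surfaces here are reproducible by construction but not bit-identical to
any particular GIS rendering.

## Orchestration and reproducibility (`demescope.pipeline`)

One global seed expands into independent per-stage streams via
`numpy.random.SeedSequence(seed, spawn_key=(stage,))`, so toggling stages
does not shift the randomness of the others; the serialized config is
written into every output directory and rerunning it reproduces all
outputs byte-identically (asserted by checksum in the tests). A failing
stage halts the run naming the stage, with earlier artefacts retained.

## Validation scale and what it shows

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen to finish in minutes on one CPU: 2,000–6,000 sites and 20–85
individuals for recovery studies, 50 replicates for the F_ST recovery
(two demes at Balding–Nichols θ = 0.10, 30+30 individuals, 2,000 loci,
recovered within ±0.02), 20,000 sites for the two-fold inbreeding
contrast (ratio 2.0 ± 5%), 500 replicates × 999 permutations for the
Mantel null calibration (type-I rate within [0.03, 0.07] at α = 0.05),
and a 40×40 grid for the planted low-heterozygosity deme, which must
produce a negative z-score basin over that deme's centroid and the lowest
deme-mean H_O.

Passing these tests shows the estimators are correct under the generative
model — it does not show robustness to what the generator omits:
linked loci (sites are exchangeable here; no LD), genotyping error that
correlates with depth or allele balance, reference bias, batch effects
between tissue sources, or coalescent noise shared between nearby loci.
The generator is a statistical emulator of a genotyped cohort, not a
sequence-level or coalescent simulator (no reads, no recombination maps,
no selection), and its isolation-by-distance knob is a free parameter,
not a calibration to any real landscape.

## Known limitations

- Runs of homozygosity are deliberately out of scope: the intended input
  is RAD/short-contig data where segments longer than the contigs cannot
  be observed; the invariant-site H_O estimator is the appropriate
  diversity measure at that fragmentation level.
- Kinship classification near band edges is inherently ambiguous between
  parent–offspring and full sibs (see above); downstream decisions should
  use the K/K0 values, not only the label.
- The F_ST bootstrap resamples loci, not individuals; with very few
  individuals per deme the CI understates sampling error in p̂.
- Mantel tests inherit their usual caveats under spatial autocorrelation
  within both matrices; scopes with fewer than 5 samples are skipped.
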