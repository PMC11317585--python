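# Methods

## The Wright–Fisher model

`simcore` simulates a closed population of `N` diploid individuals with
separate sexes, discrete non-overlapping generations and constant size
(soft selection). Each of the `N` offspring of a generation independently
draws a mother uniformly among females and a father among males with
probability proportional to male fitness — a Wright–Fisher scheme in which
selection acts through male mating/viability advantage and polygyny is
unconstrained. Offspring sex is Bernoulli(`sex_ratio`, default 0.5).

Two biallelic loci segregate, with no mutation, migration or linkage:

- *m1*: autosomal, transmitted Mendelianly (each parent passes a mutant
  allele with probability g/2).
- *m2*: X-linked by default. A mother passes one of her two X's to every
  offspring; a father passes his single X to daughters only. Males are
  hemizygous (g₂ ∈ {0,1}) and express the allele fully. An autosomal *m2*
  variant (dominance `h2`, default 1.0 so that the male-expression
  semantics d₂ ∈ {0,1} carry over at homozygosity) is available.

Male fitness uses dominance-weighted expression levels d = 0, h, 1 for
genotypes 0/1/2 (d₂ = g₂ for hemizygous males):

- `single_m1` / `single_m2`: 1 + s·d (only the named locus is selected).
- `additive`: 1 + s·d₁ + s·d₂.
- `nonadditive`: 1 + s·max(d₁, d₂) — expressing the second silencing
  phenotype adds nothing once one is expressed.
- `negative`: 1 + s·max(d₁, d₂) − c·[d₁>0 and d₂>0] — nonadditive benefit
  with an additively combining pleiotropic cost `c`.

Female fitness is always 1 (the benefit of silencing is male-limited); a
`female_selection` switch applies the same fitness function to females and
exists for self-consistency checks (male-limited selection at `s` matches
sex-shared selection at `s/2` for an autosomal locus).

The combined-fitness rule for partially expressing males is a modeling
choice the empirical description does not constrain: `max(d₁, d₂)` with
the both-expressed indicator is the minimal rule that reproduces the
defining endpoints — 1.6 / 1.3 / 1.2 for a fully expressing male at
s = 0.3, c = 0.1 — while behaving sensibly for heterozygotes at
intermediate dominance. Whether the negative-mode cost should also apply
to females is likewise unstated; here it does not (the cost is framed as a
property of the doubly expressing male phenotype).

Default parameters are the study conditions: N = 500, s = +0.3,
h₁ ∈ {0.5, 0.75, 1} (0.75 default), c = 0.1, each mutation introduced as
single copies into 5 distinct males (`n_init`), frequencies checkpointed at
generations 100 and 250. Allele frequencies use denominator 2N for
autosomes and 2N_f + N_m for the X (recomputed per generation from the
realized sex counts); male carrier fractions (≥1 copy, and both-carrier)
are recorded alongside because field observations of phenotype frequencies
are carrier proportions.

### Replication and randomness

Every replicate has its own generator:
`default_rng(SeedSequence([base_seed, scenario_index, replicate, retry]))`.
Experiments are therefore order-independent and any single replicate can be
rerun in isolation. A generation consisting of a single sex aborts the
replicate (probability ≈ 2^−(N−1), relevant only at small N); it is rerun
with `retry` incremented and the retry count is reported per row. Once both
loci are absorbed (frequency 0 or 1) the trajectory is filled forward
without further simulation, which cuts run time several-fold in selective
scenarios.

### What the simulations do and do not show

The experiment exposes the interference effect in the printed medians: at
generation 100 the per-mutation medians under additive benefits or a single
mutation sit far above nonadditive, which sits above negative. Two
fine-grained caveats, both reproducible and biological rather than
numerical: (i) even under additive benefits, m1 spreads very slightly
slower than in the single-mutation control, because selection on the
co-segregating m2 adds variance to male reproductive success
(Hill–Robertson interference); (ii) in the negative mode at later
generations (250) the surviving mutation's own median can exceed the
nonadditive mode's, because the joint-expression cost drives winner-take-
all dynamics — usually the autosomal m1 wins (its selected copies spend
1/2 rather than 1/3 of their time in males) and then sweeps unimpeded.
The impediment at generation 250 is therefore asserted on the combined
spread of the two mutations and on m2, not on m1 alone.

## The synthetic genomic architecture

`synthpop` generates diploid 0/1/2 dosage matrices emulating the empirical
system's signatures without coalescent realism. A chromosome (default
`chr2`, 120 Mb, 1,200 SNPs — a ~200× thinned stand-in for the real SNP
density) carries an inversion spanning 7.5–80 Mb segregating at frequency
`q` (default 0.4). The two arrangements are modeled as non-recombining
haplotype pools: a fraction `d` (default 0.3) of inversion SNPs is
divergent — allele frequency `theta` (0.05) on the standard arrangement vs
1 − `theta` on the inverted — and all other SNPs share a common
Uniform(0.1, 0.9) frequency. Haplotypes are drawn SNP-independently given
the arrangement; recombination suppression is thus represented by the
arrangement-conditional draw itself, not by simulating crossovers. This
reproduces exactly the downstream observables that matter: three PCA
clusters, elevated heterokaryotype heterozygosity, and strong
arrangement-tagged LD confined to the region.

A biallelic causal locus at 65 Mb rides the phase-designated arrangement
with probability `causal_linkage` (0.95): "coupling" populations carry it
on the inverted arrangement, "repulsion" populations on the standard one,
flipping the sign of every inversion–phenotype association between
populations while leaving the causal locus itself consistently associated.
The default spec generates two 90-male populations with opposite phase.
Phenotypes follow a dominant incomplete-penetrance model: carriers express
with probability `penetrance` (0.9), non-carriers at a `background` rate
(0.02); a recessive option exists. Penetrance below 1 produces
carrier-but-wild-type samples, the analogue of the handful of misclassified
individuals in real data.

On an X chromosome, males draw a single haplotype stored as doubled dosage
(0/2), so one matrix type serves both chromosome types; VCF export writes
male X calls haploid ("0"/"1") and import re-doubles them. Coordinates are
1-based inclusive (VCF convention); window arithmetic is half-open.

What the generator does **not** emulate: LD decay with distance within an
arrangement, allele-frequency spectra from demography, genotyping error
beyond uniform missingness, multiallelic sites, or breakpoint-adjacent
read signals. Tests passing on these data show the statistics recover a
planted architecture of realistic effect size — not that they would be
equally powered on real sequencing data.

## Statistics

- **Association** (`assoc`): per SNP, OLS of the 0/1 phenotype on additive
  dosage over pairwise-complete cases; the Gaussian LRT statistic
  n·ln(RSS0/RSS1) is referred to χ²(1). Monomorphic or n < 3 sites are
  flagged, not fitted. Bonferroni m = SNPs tested in the invocation.
  The χ²(1) reference is asymptotic: its O(1/n) error is visible to a
  5,000-SNP KS test at n ≈ 100, so the calibration test runs at n = 400,
  where the approximation is uniform to sampling precision. "99.9%
  outliers" default to the empirical top 0.1% of LRT statistics; a nominal
  p < 0.001 reading is available (`method="nominal"`).
- **F_ST** (`popscan`): Weir & Cockerham (1984) two-group variance
  components a, b, c per site, windowed as Σa/Σ(a+b+c) (the vcftools
  "weighted" estimator) in half-open fixed-bp windows (default 10 kb/10 kb)
  tiled from the region start; empty windows are reported as missing so
  coordinates are reproducible. Sites monomorphic over both groups or with
  fewer than two genotypes in a group are excluded. θ is exactly 1 at a
  fixed difference and can be slightly negative for identical groups (an
  unbiased-estimator property, not an error).
- **LD**: composite (genotype) r² — phase is never assumed — with
  monomorphic SNPs skipped and uniform-in-index downsampling (fixed seed)
  above `max_snps`.
- **PCA**: SVD of the per-SNP mean-centered (optionally Patterson-scaled;
  plain centering default) dosage matrix, missing values mean-imputed.
  Component signs are fixed by making each component's largest-magnitude
  loading positive, so coordinates are reproducible up to that rule.
- **Karyotype inference**: deterministic 1-D 3-means on PC1, centers
  initialized at the 10th/50th/90th percentiles, clusters ordered by mean
  PC1 → dosage 0/1/2, with a mean-silhouette separation score. The 0↔2
  labeling is identifiable only up to the arrangement flip (PC1 does not
  know which arrangement is "standard"); accuracy against truth is
  evaluated up to that flip. If fewer than three clusters remain occupied
  the call degrades to the occupied count.
- **Inversion call**: positive when all three signatures exceed thresholds
  (silhouette ≥ 0.6, heterokaryotype/homokaryotype het ratio ≥ 1.5,
  within-region over flanking mean r² ratio ≥ 2) with three occupied
  clusters. The numbers are reported either way.
- **Wilcoxon**: rank-sum test of inversion dosage between phenotype
  groups, normal approximation with tie and continuity corrections
  (adequate at the n ≈ 30 group sizes of interest; tests compare it
  against exact enumeration and a permutation null). The rank-biserial
  effect 2U/(n₁n₀) − 1 is reported signed, so coupling and repulsion
  populations produce opposite signs.

## Problem sizes

Simulation-based checks run at reduced scale chosen to keep the full suite
comfortably reproducible on a single CPU while leaving Monte-Carlo error
well below the asserted margins: 2,000 replicates for the main scenario
comparison (medians of a [0,1]-valued distribution are stable to ±≈0.02
at that size), 1,000 for the dominance-grid variants, 2,000/5,000 for the
neutral-conservation and fixation checks (3-SE bands), and 500 per
scenario in the acceptance script. The synthetic genomic datasets use
1,200 SNPs × 180 samples.

## Known limitations

- The simulator supports exactly two loci and the five fitness modes; no
  mutation, migration, age structure or explicit genetic map.
- The Gaussian LM on a binary phenotype is the analysis of record here
  (a logistic fit is a natural extension, not implemented).
- The F_ST estimator is the two-group specialization; it treats the
  doubled male-X encoding as diploid (het-free), so X-based F_ST is an
  approximation and the shipped scans use autosomal groups.
- `detect_inversion` requires heterokaryotypes; an all-male X-chromosome
  sample (karyotypes 0/2 only) yields two PCA clusters and a negative
  call, mirroring the fact that such data support an inversion only
  through LD reasoning.
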