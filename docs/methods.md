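# Methods

## Problem and overall design

`rarewin` tests whether clusters of rare variants (RVs, sample minor allele
frequency < 0.05) near disease-associated common variants (CVs, MAF ≥ 0.05)
are associated with a binary phenotype such as hypertension, and whether that
signal differs between index markers located inside genes and outside them.
The analysis proceeds in fixed stages:

1. **QC** — multi-allelic sites (≥ 2 ALT alleles) excluded; exact
   Hardy-Weinberg test at p < 0.01 (all subjects pooled); per-visit binary
   indicators collapsed to any-visit 1/2 codes (2 if the condition appears at
   any of up to four visits, 1 if every observed visit is negative, missing if
   nothing observed).
2. **Scan** — per-CV logistic regression of affection on minor-allele dosage,
   adjusted for smoking, blood-pressure medication, age at first visit and
   sex; Wald p on the dosage coefficient; no multiple-testing correction (the
   scan only ranks markers); the top K = 10 become index markers.
3. **Windows** — closed intervals of half-width 1, 5 and 25 kb around each
   index marker. Members are RVs in the interval, excluding the index itself
   and excluding singletons (exactly one minor-allele copy in the sample).
   Windows with fewer than two members are reported "n/a".
4. **C-alpha** — per window, T = Σᵢ[(yᵢ − nᵢp₀)² − nᵢp₀(1−p₀)] with yᵢ the
   minor-allele copies in cases, nᵢ the copies overall, and p₀ the proportion
   of cases among subjects. The exact binomial-enumeration variance c and the
   one-sided asymptotic Z = T/√c are reported as diagnostics; inference uses
   permutation: p = (1 + #{T_b ≥ T_obs})/(1 + B), B = 1000 by default, ties
   counting against rejection.
5. **Biased urn** — permutations preserve population structure: case sets of
   the observed size K are drawn with probability proportional to the product
   of per-subject odds weights (multivariate Fisher noncentral hypergeometric
   = conditional Bernoulli law). Weights are the fitted odds from a logistic
   regression of status on the first 5 PCs of an LD-pruned marker panel
   (pairwise r² ≤ 0.01, variants with missing calls dropped) plus the clinical
   covariates, with fitted probabilities clipped to [1e−6, 1−1e−6].
6. **Comparison** — per window size, a 2×2 table of significant (permuted
   p < 0.05) vs not, in-gene vs not-in-gene, tested with the two-sided
   Fisher exact test under the probability-mass rule (sum of all tables with
   the observed margins no more probable than the observed one, with a 1e−7
   relative tolerance on the comparison).

## Key modelling choices

* **p₀ is the case share of subjects**, not of chromosomes. Both conventions
  appear in the overdispersion-test literature; this package follows the
  subject-share definition throughout (the permutation null makes the test
  exact either way; the choice only shifts T's centring).
* **One-sided upper tail.** The mixture alternative (some variants
  deleterious, some protective) inflates the spread of the yᵢ and hence T
  upward; underdispersion is not evidence for association.
* **Window = half-width.** "A w-kb window around a marker" is read as
  ± w kb (radius), the common convention for windows centred on a point.
* **Singletons** (nᵢ = 1) are removed before counting window members: a
  variant seen once cannot be over- or under-dispersed. Windows are counted
  after removal, so "n/a" rows are those left with ≤ 1 RV.
* **Applicability and the comparison.** Inapplicable windows are excluded
  from the 2×2 tables by default (`count-nonsignificant` is available). On
  the published benchmark outcomes shipped in `rarewin.published`, both rules
  reproduce the printed 5-kb (p = 1) and 25-kb (p = 0.5238) Fisher values,
  which involve no inapplicable windows; the printed 1-kb value (0.4667) is
  not recovered by either rule (exclusion gives 0.4286, counting gives
  0.4444), so the 1-kb comparison is treated as unresolved and is not used
  for validation.
* **Exact HWE test** (conditional on allele counts, two-sided by probability
  mass) rather than chi-square: the intended cohort size is ~100 subjects,
  where the exact test is the field standard. It is applied to all subjects
  pooled, after subject subsetting.
* **Exact urn sampling.** The conditional Bernoulli draw uses the log-space
  elementary-symmetric-polynomial recursion (table O(N·K), draw O(N)); no
  rejection or MCMC, so the sampled law is exact up to floating point and is
  validated against full subset enumeration at N = 8.
* **Wald tests** in the scan (the likelihood-ratio test is cross-checked in
  the test suite); complete-case handling of missing covariates; fits that
  separate or fail to converge are flagged, never silently dropped or forced.
* **LD pruning** is greedy left-to-right with a comparison window of the 500
  most recently kept variants — deterministic and adequate for one
  chromosome. Pruning exists to approximate marker independence for PCA on
  real data; the synthetic cohorts simulate background CVs independently
  given ancestry, so the simulation studies compute PCs on the full common
  panel (pruning at r² ≤ 0.01 near the null-noise level n⁻¹ would otherwise
  discard precisely the ancestry-informative markers at desk-scale n).

## The synthetic cohort generator

The generator (`rarewin.synth_cohort`) emulates the data the pipeline is
designed for, since the motivating cohort is not publicly distributable:

* **Genotypes**: Balding–Nichols model. Each variant draws an ancestral
  frequency (CVs uniform on [0.1, 0.5], RVs on [0.005, 0.03], so expected RV
  MAF < 0.05 by construction); each of `n_subpops` subpopulations draws its
  own frequency from Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes are
  Hardy-Weinberg binomials within subpopulation. Defaults: 103 subjects, two
  subpopulations, F = 0.05.
* **Layout**: ten RV clusters of 30 variants spread over ±25 kb around an
  index CV, cluster centres 150 kb apart (so 25-kb windows never bridge
  clusters), plus 120 background CVs placed uniformly outside cluster spans.
  Gene intervals cover alternate clusters, so five index markers are in-gene.
* **Effects**: within each cluster, 50% of RVs deleterious (OR 3 per copy),
  20% protective (OR 1/3), 30% neutral (largest-remainder allocation, then a
  random arrangement); index CVs carry OR 2. These are the mixture conditions
  the windowed test targets.
* **Phenotypes**: logistic liability = intercept + covariate terms (sex 0.3,
  age 0.02/yr, smoking 0.4, medication 0.5 log-odds) + Σ β·dosage + optional
  per-subpopulation shift. The intercept is calibrated by bisection so the
  expected case fraction equals the target (default 60/94 ≈ 0.64, the
  case:control balance of the motivating cohort). Per-visit indicators are
  then derived from the collapsed status (visit-level detection probability
  0.7 for hypertension, 0.85 for smoking/medication, with one visit forced
  positive for latent positives) — the analysis only consumes the collapsed
  coding, so visit noise never flips a subject's status.
* **Seeding**: one master seed, split with `numpy.random.SeedSequence` into
  per-stage child streams; all outputs byte-identical under a fixed seed.

What the generator does **not** emulate: linkage disequilibrium within the
background panel (variants are independent given ancestry), relatedness,
genotyping/sequencing error, missing genotype calls, quantitative covariate
confounding with ancestry, and realistic gene annotation density. Passing
simulation studies therefore demonstrate correctness and calibration of the
statistical machinery under the stated generative model, not performance on
any particular real cohort.

## Simulation studies (`rarewin.studies`)

Problem sizes are fixed, desk-scale choices:

* **Sampler exactness**: N = 8 subjects, K = 4 cases, weights spanning
  0.1–9 (the order-of-magnitude spread logistic urn weights show under
  visible stratification), 20,000 draws against the enumerated 70-subset law.
* **Null calibration**: 400 cohorts of 150 subjects, one 15-RV neutral
  cluster, homogeneous population; 25-kb window, B = 500 uniform
  permutations; rejection at 0.05 expected in [0.03, 0.07].
* **Stratification**: 200 cohorts of 200 subjects, two subpopulations,
  F = 0.1, liability shift ∓1 (case prevalence ≈ 0.35 vs 0.75), neutral RVs;
  naive permutation is anticonservative (rejection ≈ 0.4) while the
  biased-urn test returns to nominal (≤ 0.07). PCs from the cohort's 400
  background CVs.
* **Power**: 100 cohorts per sample size (250 and 1000 subjects) under the
  default deleterious/protective/neutral mixture, with a matched neutral
  null at each size.

## Numerical notes

* Permutation T values are compared with T_obs using a 1e−9 relative
  tolerance so exact ties (common under label symmetry) count against
  rejection regardless of summation order.
* `calpha_variance` groups equal nᵢ before enumeration; the naive per-variant
  path is kept in the tests as the oracle.
* HWE and urn computations run in log space (`gammaln`, `logaddexp`) to stay
  finite at any count or weight the clipping allows.
* PCA standardises genotype columns by √(2f(1−f)), mean-imputes missing
  calls, drops monomorphic columns, and fixes each score's sign by making its
  largest-magnitude entry positive; rank deficiency returns fewer components
  with a warning.
* Monomorphic variants pass QC (HWE p = 1) but can never qualify as CVs or as
  non-singleton RVs, so no explicit rule is needed.

## Known limitations

* The scan fits each marker with a full IRLS; for hundreds of thousands of
  markers a score-test screen would be preferable.
* The urn stage requires complete status/covariate data; subjects failing
  that are dropped from testing (their count is logged), matching the
  complete-data reduction the design anticipates.
* `classify_gene_membership` scans intervals linearly — fine for gene tracks
  of desk-scale size, not for genome-wide annotation.
* The conditional-Bernoulli table is rebuilt per (N, K) pair; repeated calls
  within one permutation run share it via a cache, but independent windows
  rebuild it (cheap at N ≈ 100).
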