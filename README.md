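# rarewin

Windowed rare-variant association testing around common-variant index markers,
with the C-alpha overdispersion test and a stratification-adjusted (biased
urn) permutation null.

## The problem

Single-marker logistic regression works for common variants (CVs, minor allele
frequency ≥ 0.05) but is underpowered for rare ones (RVs, MAF < 0.05). A
standard remedy pools the RVs in a region and tests them jointly; burden-style
tests lose power when a region mixes risk and protective alleles. The C-alpha
test targets exactly that mixture. `rarewin` implements a pipeline built on
it for case-control cohorts with longitudinal binary phenotypes:

1. **QC** — exclude sites with ≥ 3 alleles and variants failing an exact
   Hardy-Weinberg test (p < 0.01); collapse per-visit indicators to any-visit
   1/2 codes.
2. **Scan** — per-CV logistic regression of affection on minor-allele dosage,
   adjusted for smoking, blood-pressure medication, age at first visit and
   sex; rank by Wald p and keep the top 10 as index markers.
3. **Windows** — ±1, ±5 and ±25 kb around each index marker; members are the
   RVs inside, minus the index itself and minus singletons; windows with < 2
   members are reported `n/a`.
4. **C-alpha** — for window variants i with nᵢ minor-allele copies overall and
   yᵢ in cases, and p₀ the case share of subjects,

       T = Σᵢ [ (yᵢ − nᵢp₀)² − nᵢp₀(1−p₀) ]

   tested one-sided (overdispersion) by permutation of case labels with the
   case count fixed.
5. **Biased urn** — permutations that respect population structure: case sets
   are drawn from the multivariate Fisher noncentral hypergeometric
   (conditional Bernoulli) law with per-subject odds weights fitted from the
   top 5 principal components of an LD-pruned panel plus the clinical
   covariates. Sampling is exact (elementary-symmetric-polynomial recursion),
   not rejection-based.
6. **Comparison** — per window size, a 2×2 table of significant (permuted
   p < 0.05) versus not, split by whether the index marker lies in a gene
   (anywhere within the 5′–3′ UTR span), tested with the two-sided Fisher
   exact test.

Because the motivating cohort data are access-restricted, the package ships a
synthetic cohort generator (`rarewin.synth_cohort`) with the same structure:
latent subpopulations (Balding–Nichols divergence), associated index CVs,
RV clusters mixing deleterious/protective/neutral effects, and four-visit
binary phenotypes. See `docs/methods.md` for the model and all defaults.

## Worked example

```sh
rarewin simulate --out demo --seed 19      # VCF + BED + subjects + truth
cat > demo/config.yaml <<EOF
vcf: demo/cohort.vcf
bed: demo/genes.bed
subjects: demo/subjects.tsv
out_dir: demo/out
seed: 19
EOF
rarewin run --config demo/config.yaml
```

prints one line per window size plus the report paths:

```
width=1000   table=(0, 0, 0, 0)   fisher_p=n/a
width=5000   table=(1, 1, 0, 3)   fisher_p=0.4
width=25000  table=(1, 2, 0, 5)   fisher_p=0.375
```

Each `table` is (in-gene significant, in-gene not, not-in-gene significant,
not-in-gene not) at α = 0.05 over the applicable windows; `fisher_p` is the
two-sided Fisher exact p for that table (`n/a` when every 1-kb window in this
103-subject cohort was left with ≤ 1 rare variant after singleton removal —
small windows at small n genuinely carry too few RVs, which is itself one of
the pipeline's findings about window-size sensitivity). The per-window detail
lands in `demo/out/window_results.tsv`:

```
marker      width  in_gene  n_rv  applicable  T          Z          p_asymptotic  p_permutation
v00533452   5000   False    4     True        0.324819   0.177506   0.429555      0.360639
v00533452   25000  False    9     True        -0.810255  -0.256964  0.601397      0.512488
...
```

`T` is the C-alpha statistic (negative values mean the rare-allele case
shares were *less* dispersed than binomial), `Z = T/√c` the asymptotic
standardisation kept as a diagnostic, and `p_permutation` the biased-urn
permutation p (B = 1000) that the comparison stage consumes.

The same steps are available as library calls (`rarewin.simulate_cohort`,
`rarewin.run_pipeline`, or the per-stage functions in `rarewin.qc`,
`rarewin.assoc`, `rarewin.windows`, `rarewin.calpha`, `rarewin.urn`).

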