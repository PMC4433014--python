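# Methods

## The PDT and its set-level extension

The single-SNP pedigree disequilibrium test (PDT) summarizes, per nuclear
family, the over-transmission of one allele (A1, by convention the minor
allele) to affected children and its excess in affected versus unaffected
siblings. A triad contributes only when both parents are genotyped and at
least one is heterozygous; a discordant sib pair (DSP) contributes only when
the two sibs' genotypes differ. For genotype *counts* f, m, c the triad score
is 2c − f − m, which equals (transmitted A1) − (untransmitted A1) over both
meioses; the DSP score is the affected minus the unaffected count. The family
summary D averages the unit scores, so |D| ≤ 2, and T² = (ΣD)²/ΣD² is
asymptotically χ²(1) under the null of no linkage or no association. A family
contributes both triads and DSPs when it has both; all affected × unaffected
sib pairs are counted (not a matching), matching the statistic's original
definition.

The set-level test evaluates, at each threshold k in a strictly decreasing
grid (default 0.05, 0.03, 0.01, 0.005), Y_k = Σ T² over the SNPs with
single-SNP p < k (strict), standardizes against the permutation null, and
takes M = max_k Z_k. Four thresholds are the default because a ten-threshold
grid buys little power at a real computational cost; the grid is
configurable.

## The sign-flip permutation

Swapping the transmitted and non-transmitted parental haplotypes for all
children of a family negates that family's D at every SNP simultaneously and
leaves everything else (parental genotypes, informativeness, LD structure,
sib IBD) untouched. One fair sign per family applied to its whole D-matrix
row is therefore an exact draw from the null orbit, and a single pass of m
sign vectors serves every threshold — which is what makes M and the permuted
M_j comparable. Because ΣD² is sign-invariant, the permuted per-SNP T² only
needs the flipped column sums, and threshold selection "p < k" is applied as
"T² > χ²₁⁻¹(k)", avoiding per-cell tail evaluations. Mendelian-inconsistent
triads are excluded at the offending marker (tallied and reported); DSPs in
the same family are kept. This per-marker exclusion keeps the sign symmetry
of D intact.

## Estimators and edge cases

* μ̂_k is the permutation mean and σ̂_k the sample standard deviation
  (m − 1 denominator); a threshold with σ̂_k = 0 is excluded from the max for
  both the observed and every permuted statistic, preserving exchangeability.
* An empty L_k gets Y_k = 0 (empty-sum convention) both observed and in
  permutations, so the null moments are always estimated from all m draws.
  When *every* observed L_k is empty the test returns p = 1; this is not a
  special case but the value the convention computes (every permutation's
  Y ≥ 0 = Y_obs, hence every M_j ≥ M).
* The p-value is #(M_j ≥ M)/m with ties counted as exceedances; an
  `estimator="add-one"` switch gives (r+1)/(m+1). Output always carries the
  minimum attainable p (1/m) so a reported 0 is interpretable. Default
  m = 2000; no adaptive early stopping, so p is exactly reproducible under a
  seed. Like any plain Monte-Carlo permutation p without the observed draw
  in the numerator, the estimator's calibration degrades as m shrinks, so
  experiment defaults keep m at 1000 or above.
* Untestable markers (no informative family) get p = 1 and can never enter
  any L_k; a fully untestable set returns p = 1.
* Per-set RNG streams are derived from (seed, set name) via SHA-256, so
  multi-set runs are bit-identical for any worker count or execution order.
* An exhaustive-enumeration variant over all 2^N sign vectors serves as an
  exact reference for N ≤ 20 families and anchors the Monte-Carlo engine in
  the test suite.

## I/O conventions

PLINK PED/MAP and BED/BIM/FAM (SNP-major v1.00) are read and written
natively. In binary files the counted allele is BIM column 5 (A1) and the
2-bit codes follow PLINK semantics: 00 = homozygous A1, 01 = missing,
10 = het, 11 = homozygous A2, least-significant bits first. For text input
the counted allele is the sample minor allele; the squared statistic makes
every result invariant to this choice (relabeling negates D, T² unchanged),
which the property tests assert. Only two-generation families are accepted;
deeper pedigrees are rejected with an explicit error because the sign-flip
argument does not extend to them. A child with exactly one genotyped parent
contributes no triads (two genotyped parents are required) but its DSPs are
kept. Gene-to-marker assignment uses 1-based closed intervals with optional
symmetric padding (default none).

## The simulator

The generator emulates a two-step family-GWAS simulation: a fixed pool of
10,000 haplotypes, then random mating, gene dropping and rejection sampling
of families.

* **Haplotype pool.** A latent AR(1) Gaussian (default ρ = 0.8) thresholded
  at per-marker quantiles gives each marker its target MAF and geometric LD
  decay with marker distance; the latent chain restarts at gene boundaries so
  LD does not leak across genes. This reproduces the *statistical shape* of
  reference-panel haplotypes — controllable MAFs, strong local LD, decay with
  distance — but not any real panel's haplotype frequencies, so power numbers
  are comparable across methods run on the same replicates, not to numbers
  obtained from real reference data.
* **Scales.** Presets cover the two study scales (46 SNPs in 1 gene;
  1207 SNPs across 10 genes), three structures (nuclear = 2 parents +
  1 affected + 2 unaffected sibs; triad; discordant sibship = same sibship
  with both parents missing), and the standard disease-SNP MAF lists
  (5 SNPs: 0.1, 0.13, 0.2, 0.4, 0.42; 10 SNPs: 0.04 ... 0.43). Non-disease
  MAFs are drawn once per study from U(0.05, 0.5). Disease SNPs are placed at
  evenly spaced positions (or selected by the MAF > 1% / pairwise r² < 0.1
  rule when chosen at random; the r² cap is a config value).
* **Penetrance.** P(Affected | X) = expit(α + B·X) with per-SNP coding
  additive 0/1/2, dominant 0/1/1, recessive 0/0/1 of risk-allele (minor
  allele) copies and no interaction terms. The intercept α is calibrated by
  bracketed root finding so that the random-mating population prevalence hits
  the target (default 5%), with the expectation over a 200,000-genotype
  Monte-Carlo sample; with all effects zero the closed form logit(prevalence)
  is used. Affection is sampled per child *before* ascertainment, and a
  family is kept only if it matches the structure's affected/unaffected
  counts (cap of 10⁶ attempts per family).
* Gene dropping uses no within-gene recombination: sets are gene-scale where
  recombination is negligible, and the permutation's validity — not the
  simulator — is what handles recombination in principle.

## Experiments

The harness builds the haplotype pool and calibrates the intercept once per
scenario and draws fresh families per replicate (one panel, many samples),
which is both the natural reading of the two-step design and what makes
desk-scale replication affordable. All methods in a power comparison see the
identical replicate studies (seeds derived from the replicate index), so
power differences are paired. Comparators are the fixed-threshold sum test
(the single-threshold special case of the engine, standing in for PLINK-style
set tests — the "top independent SNPs averaging" refinement is not
replicated), and Fisher, Simes and Bonferroni-min-p combinations of the
per-SNP PDT p-values. Rejection rates carry exact Clopper–Pearson 95%
intervals.

Default problem sizes: type I error uses 500 replicates × 500 triads ×
46 SNPs with m = 1000; the power ordering check uses 250 replicates per odds
ratio at the 10-gene scale with m = 500. Replicate counts and m are scale
knobs, not properties of the method.

## Known limitations

* Nuclear families only; no extended pedigrees, no quantitative traits,
  no X-chromosome handling, no dosage/VCF input.
* Designed for common variants (the single-SNP p-values that drive selection
  are uninformative for rare variants).
* The simulator's AR(1) LD model cannot reproduce real haplotype block
  structure (recombination hotspots, allele-frequency spectra of a real
  population), so simulation results validate calibration and relative
  ordering, not absolute power on real data.
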