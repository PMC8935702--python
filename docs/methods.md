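# Methods

## Prevalence model

All three estimators target the affected frequency φ of an autosomal
recessive disease, equal to q² under Hardy–Weinberg equilibrium (HWE) when
q is the aggregate pathogenic allele frequency. Their shared assumptions:

- **One pathogenic allele per carrier.** Cohort summaries record carriers
  (individuals with ≥1 pathogenic/likely-pathogenic allele). The allele
  count used by the Bayesian estimator is x = C out of n = 2N. For a
  disease-free cohort and rare alleles the probability that a carrier holds
  two pathogenic alleles is O(q²) and ignored; individual-level input can
  override this.
- **Random mating, no consanguinity, full penetrance.** The couple's
  carrier risk is the plain product of two carrier frequencies, and a
  quarter of a carrier-couple's offspring are affected.

Estimators 1 and 2 are method-of-moments: (C/N)²/4 unstratified, or the
product of the male and female carrier frequencies over 4. They coincide
exactly when carriers split proportionally between genders. Estimator 2
deliberately refuses cohorts with an empty gender stratum rather than
falling back to estimator 1, so a missing stratum is never papered over.

### Bayesian estimator

Conjugate Beta–binomial: prior Beta(α₀, β₀) on q, posterior
Beta(x+α₀, n−x+β₀). Defaults and conventions:

- **Prior: Jeffreys, α₀ = β₀ = 0.5.** It is the invariant reference prior
  for a binomial proportion, and with the published cohort counts it
  reproduces the published point estimates to the displayed digit
  (children: ((110.5)/41811)² → 1/143,171). The prior is a plain parameter
  for users who prefer uniform (1, 1) or informative pseudo-counts.
- **Point estimate: squared posterior mean of q.** Alternatives
  (posterior mean of q², squared posterior mode) are available behind the
  `point` option; they differ in the third significant digit at these
  sample sizes (E[q²] = Var(q) + E[q]² is always larger; the mode is
  smaller for the right-skewed posteriors rare alleles produce).
- **Interval: equal-tailed quantiles, not HPD.** The credible interval on
  q is mapped to φ through q ↦ q², valid because the map is monotone on
  [0, 1]. Equal tails keep the reciprocal rendering interpretable
  ("1/212,000 to 1/100,000") and match the published bounds to ~1%.
- **Reciprocal rendering** rounds 1/φ half away from zero and is display
  only; all arithmetic and tests run on frequencies. Averages of several
  estimates are arithmetic means of frequencies, never of reciprocals.

## Allele-frequency comparison

Per-variant cross-cohort tables are 2×2 allele counts (alt/ref × cohort).
Defaults:

- Pearson χ² without continuity correction; `test="auto"` switches to
  Fisher's exact test when any expected cell is below 5 (the switch is
  logged). A zero row/column margin means identical frequencies and is
  reported as statistic 0, p = 1, rather than an error.
- Odds ratios at a zero comparison cell report ±infinity — the standard
  reporting convention for "absent in the other population" — with a
  Haldane–Anscombe +0.5 option for users needing finite values.
- Multiple testing: Bonferroni (p × m capped at 1), order preserved.

Panel-restricted comparison re-runs the Bayesian estimator on the alleles
each panel captures out of the same n and summarises as φ_a/φ_b. The
significance of that contrast is computed by a two-proportion Pearson χ² on
(x_a vs x_b out of n). This is a documented package convention: it is *not*
claimed to reproduce any externally published p-value for panel contrasts,
whose generating procedure is not public.

## Haplotype analysis

Phasing is consumed, never computed: input is a phased VCF ("|" separators;
any unphased genotype is an error naming sample and position). Only
biallelic SNPs are kept. Block boundaries are inputs (plink `.blocks.det`
lists or explicit SNP lists).

- **SNP filtering:** MAF ≥ 0.01 and exact HWE p ≥ 0.001, both inclusive.
  The HWE test is the exact conditional test (probability-sum form over all
  heterozygote counts compatible with the allele margin), computed in log
  space with a 1+1e−12 tie tolerance so equal-probability tables are
  included deterministically; it matches full exact-rational enumeration to
  1e−12 for all tables with ≤30 individuals.
- **Spectra:** per-block haplotype counts over 2N haplotypes; top-k
  collapse (default k = 5) merges the remainder into "other", breaking
  rank-k ties lexicographically so runs are reproducible; collapse and
  block projection conserve total counts.
- **Cross-cohort spectrum tests:** Pearson χ² over the union of categories
  (zero-total categories dropped; ≥2 categories required).
- **Joint-genotype association:** for each ordered allele pair at two tag
  SNPs (labels like "A-G" for rs213950–rs1042077), a 2×2 table of
  P/LP-carrying vs non-carrying haplotypes with vs without that background,
  tested two-sided by Fisher's exact test. This is the founder-mutation
  signature: a pathogenic allele descending from one ancestral chromosome
  is over-represented on that chromosome's haplotype background.

## Synthetic cohorts

The generator draws what the estimators assume, so tests are
parameter-recovery exercises:

- Gender ~ Bernoulli(male_fraction), default 0.5; genotypes per variant
  under HWE at the configured q (default 2.63e−3, a realistic aggregate
  pathogenic-allele rate for a rare recessive disease in a large cohort).
  Default cohort sizes in tests follow the analysis scales: 50,000 for
  coverage studies, ~21,000 (exome-cohort scale) for association.
- An `excess_homozygosity` knob (inbreeding-style F) breaks HWE for
  robustness studies, since real clinic-ascertained cohorts need not be in
  equilibrium. Homozygous-affected individuals are excluded by default,
  mirroring a screening cohort from which diagnosed patients were removed.
- Phased cohorts draw 2N haplotypes independently from an explicit pool;
  default pool over the two *CFTR* tag SNPs: AG 0.425, GT 0.370, GG 0.200,
  AT 0.005 (East-Asian-like; the rare AT is the classic F508del
  background). P/LP flags are planted with a configured marginal rate
  (default 110/41810) and enrichment odds ratio toward one background,
  solving the per-background rates by root-finding so the marginal rate is
  preserved at any odds ratio.
- One `numpy.random.Generator` seeded from the config drives every draw:
  fixed seed ⇒ byte-identical fixture bundles.

**What the generator does not emulate:** linkage disequilibrium beyond the
explicit pool, demography/coalescent structure, genotyping error, capture
non-uniformity between exome kits, and the ascertainment bias of a
patient-derived cohort. Passing round-trip tests therefore demonstrates the
estimators are correct under their stated assumptions — not that those
assumptions hold in any particular real cohort.

## Numerical and design notes

- Beta quantiles come from `scipy.stats.beta.ppf`; the test suite
  cross-checks them against an independent trapezoid integration on the
  x = sin²θ substitution (which removes the Jeffreys endpoint
  singularities) to 1e−6.
- Statistical verification in tests: method-3 95% intervals achieve
  93–97% empirical coverage of q² over 500 simulated HWE cohorts
  (q = 2.63e−3, N = 50,000); a planted background odds ratio of 2.25 at
  exome-cohort scale is recovered to within 3 standard errors of the mean
  log-OR over 30 replicates, and the null case stays at OR ≈ 1.
- Coordinates are 1-based VCF-style on the forward strand, hg19 by
  convention for the bundled *CFTR* tag-SNP defaults; no liftover is
  provided.
- TSV dialect everywhere: tab-separated, UTF-8, mandatory header, `#`
  comment lines. Readers validate and reject; they never repair.

## Limitations

- Summary-count mode cannot see compound heterozygotes or de novo events;
  prevalence from carrier counts is a lower-bound-flavoured estimate when
  penetrance is incomplete.
- The two-proportion χ² for panel contrasts treats the restricted panel's
  captured alleles as an independent sample, which overstates independence
  (the restricted set is nested); its p-values are indicative, not exact.
- The exact HWE test enumerates heterozygote counts and is O(min allele
  count); it is intended for per-SNP filtering, not genome-scale scans.
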