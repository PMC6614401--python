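# Methods

## Model

A biallelic X-linked locus with allele-1 frequency *p* contributes additive
genetic variance 2*p*(1−*p*)β_f² in diploid females and *p*(1−*p*)β_m² in
hemizygous males, where β_f and β_m are the per-allele effects on a trait
standardised to unit variance within each sex. The inactivation state of
the locus is parameterised by d ∈ [1, 2] with β_m = d·β_f: under complete
X-inactivation the two female dosage units act through a single active copy
(random mosaicism halves the effective allelic step), giving d = 2 and a
male/female variance ratio of d²/2 = 2; a locus that fully escapes
inactivation has d = 1 and variance ratio ½. A male-specific additive
deviation δ (β_m = d·β_f + δ) models loci under sex-hormonal control whose
male variance is unrelated to dosage compensation.

Aggregated over a trait's causal loci with equal female-side variance per
locus and an escape fraction π, the male/female heritability ratio is
2(1−π) + ½π and the mean per-allele effect-size ratio is 2(1−π) + π
(`expected_dc`).

## Estimators

**DC ratio.** For a per-SNP association statistic χ² = z², the expectation
over a chromosome of M SNPs is 1 + N·h²/M, so the excess mean chi-square is
proportional to N·h². The ratio

γ̂ = (χ̄²_m − 1)·N_f / [(χ̄²_f − 1)·N_m]

therefore estimates h²_m/h²_f free of the sample-size difference. Its SE is
the delta-method propagation of var(χ̄²) = (2/M_eff)[1 + 2(χ̄² − 1)], where
M_eff is the effective number of independent SNPs: the panel size for
unlinked simulated SNPs, and ≈1300 for the real human X (`M_EFF_HUMAN_X`).
When either excess mean chi-square is non-positive the ratio is flagged
undefined rather than returned negative — without polygenic signal the
estimand does not exist.

**Genetic correlation.** r̂_g = χ̄²_mf/√[(χ̄²_m−1)(χ̄²_f−1)] with χ̄²_mf the
mean cross-product of male and female Z-scores; since the two strata are
disjoint samples, the cross-product has no sample-overlap term. The SE is
a delete-one-block jackknife over contiguous position-ordered blocks;
the block count defaults to 1000 and is capped at half the SNP count so
desk-scale panels retain ≥ 2 SNPs per block.

**Effect-size ratio and heritability ratio.** β̂_m/β̂_f and ĥ²_m/ĥ²_f with
first-order delta-method SEs; both are flagged undefined at a zero
denominator.

**DC coefficient.** A no-intercept weighted least-squares fit of β̂_m on
β̂_f at selected loci; the model β_m = d·β_f has no offset, hence no
intercept. Weights are 1/SE²(β̂_m) as defined; a `both_var` option adds the
female-side variance for sensitivity analyses (the estimator is then no
longer the declared statistic, so it is never the default). Two caveats
shape experimental design:

* *Regression dilution*: β̂_f enters as a noisy regressor, attenuating the
  slope by roughly 1/(1 + 1/NCP_f), where NCP_f is the female per-locus
  association noncentrality. The recovery experiments therefore use few,
  strongly associated loci (female per-locus R² = 1.75 %, NCP ≈ 350),
  mirroring the single-eQTL architectures the coefficient is applied to in
  practice, where a single SNP can explain up to 65 % of expression
  variance.
* *Winner's curse*: selecting loci in the same stratum whose estimates are
  regressed inflates the discovery-stratum estimates, biasing the slope up
  under male discovery and down under female discovery. Combined-sample
  (inverse-variance meta-analysis) discovery splits the selection noise
  across both strata and is the default scheme; the discovery-sex designs
  are retained to demonstrate the bias direction.

**Heterogeneity.** Under full DC, ½β̂_m − β̂_f has mean zero, so
T = (½β̂_m − β̂_f)²/(¼SE²_m + SE²_f) is χ²(1) under the null. SNPs with
P < 5×10⁻⁸ seed regions comprising all SNPs with r² > 0.05 to the top SNP,
padded ±250 kb; overlapping padded regions merge, keeping the more
significant top SNP. LD is computed on pooled-sex reference genotypes with
males recoded to the diploid-style {0,2} dosage — with per-allele {0,1}
male coding every X SNP pair is spuriously positively correlated through
the sex difference in dosage means — and a female-only reference is
available (`ref_sex="F"`). After exclusion, M_eff is scaled by the
retained-SNP fraction by default (`m_eff_policy="scale"`); a pass-through
(`"keep"`) alternative is provided since either convention is defensible.

**REML.** y = g_G + g_X + ε with g_G ~ N(0, A_G σ²_G), g_X ~ N(0, A_X σ²_X).
GRMs are Z·Zᵀ/m on column-standardised dosages of the analysed individuals;
sex-stratified fits standardise within one sex, which makes the male {0,1}
vs {0,2} coding question moot and sidesteps cross-sex X-scaling entirely.
The fitter runs average-information iterations after one EM start step,
with step-halving whenever a proposed update would decrease the restricted
likelihood and an EM fallback (which cannot decrease it); components are
floored at 10⁻⁶·var(y). Convergence is a relative log-likelihood change
below 10⁻⁶ within 200 iterations; SEs come from the inverse
average-information matrix (pseudo-inverse when a component is
unidentifiable, e.g. a zero GRM).

## Association engine

Per-SNP ordinary least squares on within-sex standardised phenotypes.
Simulated individuals are unrelated, so OLS is exact and no mixed model is
needed; a covariate slot (residualisation, equivalent to joint fitting)
accepts principal components for real data. Male X non-PAR genotypes under
the diploid-style {0,2} coding give identical test statistics and
half-sized raw slopes; effects and SEs are rescaled ×2 so all reported
estimates are per-allele. SNPs at within-stratum MAF ≤ 0.01 or zero dosage
variance are dropped and counted in the log. Meta-analysis is
inverse-variance weighting after allele harmonisation (A1/A2 swaps flip
the effect sign and frequency; strand-ambiguity handling is out of scope
for simulated data). Tie-breaking everywhere is smaller p, then smaller
position, then lexicographic id.

## Simulator

Haplotypes are independent Bernoulli(p) draws — one per male, two per
female (and two for anyone on PAR/autosomes). Allele frequencies are
uniform on a MAF range (default 0.01–0.5) with random minor/major
orientation. Causal effects are scaled so the female X-linked heritability
is met exactly; with `equal_var_per_locus` (default) each causal locus
contributes equal female-side variance, making the escape-mixture
expectations exact at finite locus counts, and the escape count is
round(π·m) at seed-shuffled positions for the same reason. Residual
variance is set per sex so each sex has unit total variance; phenotypes are
also returned as within-sex Z-scores, and raw values are retained for REML.
The background polygenic term is a Normal deviate of variance h²_bg by
default; REML experiments switch to explicit autosomal genotypes so the
autosomal GRM is estimable. Optional LD uses an equicorrelated Gaussian
copula within declared blocks — adequate for clumping and region-finding
tests, and deliberately not a model of real human LD maps. Expression
traits are single-eQTL: β_f set from the female variance explained
(≤ 0.65), β_m = d·β_f, equal residual variance in both sexes — so male
expression variance genuinely exceeds female variance under DC, rather
than forcing unit variance in both sexes, which would be impossible at
variance explained above 0.5 — plus an optional female mean shift.

What the generator does *not* emulate: realistic LD maps, imputation
error, relatedness, assortment, selection-induced allele-frequency/effect
correlations, or shared environment between the sexes. Passing recovery
tests therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to those real-data complications.

## Study conditions for recovery experiments

* DCR recovery (`DCR_CONDITIONS`): 2000 unlinked X SNPs, 200 causal,
  h²_X,f = 1 %, 20 000 per sex, 20 seeds — a biobank-like polygenic trait.
  Per-seed ratios are right-skewed (the female excess mean chi-square of
  0.1 has CV ≈ 0.35), so seed-averaging pools the mean chi-squares and
  forms the ratio once, with the SE computed at the pooled effective SNP
  count.
* DCC recovery (`DCC_CONDITIONS`): 300 SNPs, 20 causal, h²_X,f = 35 %,
  20 000 per sex — eQTL-strength per-locus signal (female R² 1.75 %/locus)
  so regression dilution is negligible (see above).
* Winner's-curse demonstration (`WINNERS_CURSE_CONDITIONS`): 500 SNPs, 40
  causal, h²_X,f = 8 %, 10 000 per sex — moderate signal so that same-sex
  selection visibly biases the slope.
* Heterogeneity injection: male-specific δ ~ N(0, 0.25²) at 10 SNPs in one
  10-kb interval on the DCR background; detectable at P < 5×10⁻⁸ and large
  enough to push the naive DCR far above 2.
* REML: 1000 X + 1000 autosomal SNPs, 2000 individuals per sex — the GRMs
  are estimable and a two-component fit takes seconds; biobank-scale fits
  are explicitly not reproduced.

## Numerical and design choices

* Dosages are stored as float32 (exact for values in {0,1,2}); association
  cross-moments accumulate in float64.
* One global seed expands into per-stage child seeds through
  `numpy.random.SeedSequence`, so identical configs reproduce bit-identically
  and stages can re-run independently.
* Coordinates are 1-based closed internally (GWAS summary-file practice);
  BED export converts to 0-based half-open.
* Genotype files: VCF (male X non-PAR calls written haploid) or a
  tab-delimited triplet (samples/variants/dosages); summary statistics use
  the COJO-style `.ma` dialect (SNP A1 A2 freq b se p N) with extension
  columns preserved on round-trip.
* "Variable" escape has no canonical numeric d; `d_values` lets the user
  supply any distribution on [1, 2] instead of the two-state mixture.

## Limitations

The DCR assumes r_g = 1 between the sexes and no male-specific variance;
both failure modes are first-class here (the heterogeneity screen exists
to detect them) but the corrected DCR is still only interpretable under
the mixture model. The DCC inherits regression dilution at weakly
associated loci and selection bias under single-sex discovery. The
jackknife SE for r_g assumes approximately exchangeable blocks. REML SEs
are asymptotic information-matrix SEs and degrade near the zero boundary.
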