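# xdosage

Estimators of X-chromosome dosage compensation (DC) from sex-stratified
GWAS and eQTL association data, together with a simulator of X-linked trait
architectures under any mixture of X-inactivation states.

## The problem

Males carry one X chromosome, females two, but random X-chromosome
inactivation (XCI) silences one female copy in each cell. For a trait locus
with allele frequency *p* and allelic value *α*, haploid males contribute
genetic variance *p*(1−*p*)*α*², while mosaic females (genotype values *α*,
½*α*, 0) contribute ½*p*(1−*p*)*α*² — **half** the male variance. A gene
that escapes XCI instead expresses both female copies, and the ploidy
difference gives females **twice** the male variance. The inactivation
state of trait loci is therefore measurable from sex-stratified association
data. `xdosage` implements the estimators that do this:

* **DC ratio (DCR, γ)** — the male/female X-linked SNP-heritability ratio
  from mean association chi-squares:

      γ̂ = (χ̄²_m − 1) N_f / [(χ̄²_f − 1) N_m],

  with sampling variance of a mean chi-square
  var(χ̄²) = (2/M_eff)[1 + 2(χ̄² − 1)]. γ = 2 under full DC,
  0.5 under complete escape.
* **Male–female genetic correlation** r̂_g = χ̄²_mf / √[(χ̄²_m − 1)(χ̄²_f − 1)]
  with χ̄²_mf the mean Z-score cross-product, block-jackknife SE.
* **Effect-size ratio** β̂_m/β̂_f per SNP with a delta-method SE.
* **DC coefficient (DCC, d)** — the slope of a no-intercept regression of
  male on female per-allele effects at genome-wide-significant loci,
  weighted by the inverse variance of the male estimates; d runs from 1
  (escape) to 2 (full DC).
* **Heterogeneity test** T = (½β̂_m − β̂_f)² / (¼SE²_m + SE²_f) ~ χ²(1) under
  full DC, with LD-defined region calling and DCR/r_g re-estimation after
  exclusion — male-specific (e.g. hormonally mediated) loci otherwise
  inflate the DCR past 2.
* **Two-GRM REML** fitting y = g_G + g_X + ε to partition phenotypic
  variance into autosomal, X-linked and residual components per sex.
* **Analytic expectations**: with an escape fraction π, the expected DCR is
  2(1−π) + ½π and the expected mean effect-size ratio is 2(1−π) + π.

The simulator generates haploid-male / diploid-female X genotypes,
per-locus DC states (β_m = d·β_f, d ∈ [1,2]), optional male-specific
effect regions and LD blocks, polygenic phenotypes and single-eQTL
expression traits, so every estimator is testable by parameter recovery
without any data download.

## Worked example

```python
import xdosage as xd

cfg = xd.SimConfig(n_m=20_000, n_f=20_000, m_x=2_000, m_causal=200,
                   h2x_f=0.01, pi_escape=0.15, seed=7)
data = xd.simulate_dataset(cfg)
stats_m = xd.run_xwas(data.genotypes, data.phenotypes.y_std, xd.MALE)
stats_f = xd.run_xwas(data.genotypes, data.phenotypes.y_std, xd.FEMALE)

dcr = xd.dcr_from_stats(stats_m, stats_f)
print(f"DCR = {dcr.gamma_hat:.2f} (SE {dcr.se:.2f})")
print(xd.expected_dc(0.15))
```

prints

```
DCR = 1.41 (SE 0.42)
{'expected_dcr': 1.775, 'expected_mean_ratio': 1.8499999999999999}
```

A single replicate at this desk scale is noisy (the SE reflects the small
excess mean chi-square); `xd.dcr_recovery(0.15, n_seeds=20)` pools mean
chi-squares across 20 seeds and returns 1.78 (SE 0.16), matching the
analytic 1.775 for a 15 % escape fraction. The same session, end-to-end,
through the command line:

```sh
xdosage pipeline --config experiment.yaml --seed 7 --out run/
```

writes per-stratum `.ma` summary files, the heterogeneity table and a JSON
report with the DCR, genetic correlation, DCC per discovery scheme and any
heterogeneity regions.

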