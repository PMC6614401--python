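"""Canonical parameter-recovery experiments at desk scale.

Each function fixes one study condition (sample sizes, panel size, escape
fraction) and runs the full simulate -> associate -> estimate path, so the
same experiment backs both the test suite and reproduction scripts.

Seed handling: every experiment takes a single base seed and derives
independent per-replicate child seeds from it; identical base seeds give
bit-identical results.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .association import FEMALE, MALE, meta_analyse, run_xwas
from .dc_stats import estimate_dcr, estimate_rg, mean_chisq
from .greml import compute_grm, reml_fit
from .heterogeneity import define_het_regions, het_test_stats, reestimate_excluding
from .pipeline import COMBINED_DISC, discovery_replication
from .simulate import SimConfig, simulate_dataset


def child_seed(base_seed: int, index: int) -> int:
    """Deterministic 31-bit child seed for replicate ``index``."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1, np.uint64)[0] & 0x7FFFFFFF)


def _sex_stratified_stats(config: SimConfig, seed: int):
    data = simulate_dataset(config, seed=seed)
    stats_m = run_xwas(data.genotypes, data.phenotypes.y_std, MALE)
    stats_f = run_xwas(data.genotypes, data.phenotypes.y_std, FEMALE)
    return data, stats_m, stats_f


#: DC-ratio recovery conditions: a polygenic trait with 1% female X-linked
#: heritability spread over 200 of 2000 unlinked SNPs at biobank-like
#: per-stratum sample size.
DCR_CONDITIONS = dict(n_m=20_000, n_f=20_000, m_x=2_000, m_causal=200, h2x_f=0.01)


def dcr_recovery(
    pi_escape: float,
    n_seeds: int = 20,
    base_seed: int = 0,
    **overrides,
) -> dict:
    """Seed-averaged DC ratio under an escape mixture.

    Mean chi-squares are averaged across seeds before the ratio is formed
    (the excess mean chi-square per seed has a large coefficient of
    variation, so a ratio-of-averages avoids the Jensen bias a mean of
    per-seed ratios would carry); the standard error uses the pooled
    effective SNP count ``n_seeds * m_x``.
    """
    cond = {**DCR_CONDITIONS, **overrides}
    means_m, means_f, per_seed = [], [], []
    for i in range(n_seeds):
        cfg = SimConfig(pi_escape=pi_escape, **cond)
        _, sm, sf = _sex_stratified_stats(cfg, child_seed(base_seed, i))
        mm, mf = mean_chisq(sm), mean_chisq(sf)
        means_m.append(mm["mean"])
        means_f.append(mf["mean"])
        per_seed.append(
            estimate_dcr(mm["mean"], mf["mean"], cond["n_m"], cond["n_f"],
                         cond["m_x"]).gamma_hat
        )
    pooled = estimate_dcr(
        float(np.mean(means_m)), float(np.mean(means_f)),
        cond["n_m"], cond["n_f"], cond["m_x"] * n_seeds,
    )
    return {
        "gamma_hat": pooled.gamma_hat,
        "se": pooled.se,
        "mean_chisq_m": float(np.mean(means_m)),
        "mean_chisq_f": float(np.mean(means_f)),
        "per_seed": np.array(per_seed),
        "n_seeds": n_seeds,
        "conditions": cond,
    }


#: DCC recovery conditions: few strongly associated loci (eQTL-like per-locus
#: signal, female per-locus R^2 = 1.75%) so the per-allele effect estimates
#: that enter the regression carry negligible noise; at weak signal the
#: regression of male on noisy female estimates is attenuated toward zero.
DCC_CONDITIONS = dict(n_m=20_000, n_f=20_000, m_x=300, m_causal=20, h2x_f=0.35)


def dcc_recovery(
    pi_escape: float,
    scheme: str = COMBINED_DISC,
    n_seeds: int = 20,
    base_seed: int = 0,
    p_thresh: float = 5e-8,
    **overrides,
) -> dict:
    """Seed-averaged dosage compensation coefficient under a discovery design."""
    cond = {**DCC_CONDITIONS, **overrides}
    vals, wls_se, n_loci = [], [], []
    for i in range(n_seeds):
        cfg = SimConfig(pi_escape=pi_escape, **cond)
        _, sm, sf = _sex_stratified_stats(cfg, child_seed(base_seed, i))
        res = discovery_replication(sm, sf, scheme, p_thresh,
                                    stats_c=meta_analyse(sm, sf))
        if res.defined:
            vals.append(res.dcc)
            wls_se.append(res.se)
            n_loci.append(res.n_loci)
    vals = np.array(vals)
    return {
        "dcc": float(vals.mean()),
        "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        "mean_wls_se": float(np.mean(wls_se)),
        "mean_n_loci": float(np.mean(n_loci)),
        "per_seed": vals,
        "n_seeds": n_seeds,
        "conditions": cond,
    }


#: winner's-curse conditions: moderate per-locus signal so that selection in
#: one sex visibly inflates that sex's estimates.
WINNERS_CURSE_CONDITIONS = dict(n_m=10_000, n_f=10_000, m_x=500, m_causal=40,
                                h2x_f=0.08)


def het_injection(
    base_seed: int = 0,
    delta_sd: float = 0.25,
    region=(400_001, 409_001),
    **overrides,
) -> dict:
    """Inject male-specific effects in one interval; detect and re-estimate."""
    cond = {**DCR_CONDITIONS, **overrides}
    cfg = SimConfig(
        pi_escape=0.0,
        het_regions=[{"start": region[0], "end": region[1], "delta_sd": delta_sd}],
        **cond,
    )
    data, sm, sf = _sex_stratified_stats(cfg, child_seed(base_seed, 0))
    het = het_test_stats(sm, sf)
    regions = define_het_regions(het, data.genotypes)
    out = {"regions": regions, "het": het}
    if regions:
        out.update(reestimate_excluding(sm, sf, regions))
    return out


def reml_recovery(
    base_seed: int = 0,
    n_per_sex: int = 2_000,
    m_x: int = 1_000,
    m_auto: int = 1_000,
    h2x_f: float = 0.05,
    h2_bg: float = 0.2,
) -> dict:
    """Sex-stratified two-GRM REML on one simulated dataset, plus the
    summary-statistic DC ratio on the same data for concordance checks."""
    cfg = SimConfig(n_m=n_per_sex, n_f=n_per_sex, m_x=m_x, m_auto=m_auto,
                    m_causal=max(m_x // 10, 10), h2x_f=h2x_f, h2_bg=h2_bg,
                    pi_escape=0.0)
    data, sm, sf = _sex_stratified_stats(cfg, child_seed(base_seed, 0))
    fits = {}
    for label in ("M", "F"):
        idx = np.flatnonzero(data.genotypes.sex == label)
        a_x = compute_grm(data.genotypes.subset(individuals=idx))
        a_g = compute_grm(data.background.subset(individuals=idx))
        fits[label] = reml_fit(data.phenotypes.y[idx], [a_g, a_x],
                               names=["sigma2_G", "sigma2_X", "sigma2_e"])
    mm, mf = mean_chisq(sm), mean_chisq(sf)
    dcr = estimate_dcr(mm["mean"], mf["mean"], n_per_sex, n_per_sex, m_x)
    return {
        "fits": fits,
        "dcr": dcr,
        "true": {"sigma2_X_f": h2x_f, "sigma2_X_m": 2 * h2x_f, "sigma2_G": h2_bg},
    }
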