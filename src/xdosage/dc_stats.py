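"""Dosage-compensation estimators on sex-stratified summary statistics.

Implements the DC ratio (ratio of male to female X-linked SNP-heritability,
estimated from mean association chi-squares), the male-female genetic
correlation with block-jackknife standard errors, per-SNP effect-size
ratios, the dosage compensation coefficient (DCC: weighted no-intercept
regression of male on female per-allele effects), the heritability-ratio
standard error, and the analytic expectations under a given escape
fraction.

Scale conventions: the DC ratio is 2 under full dosage compensation and
0.5 under complete escape from X-inactivation; the DCC runs from 1
(escape) to 2 (full compensation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import SummaryStats
from .simulate import X_NONPAR

#: effective number of independent SNPs on the human X chromosome; used to
#: scale the sampling variance of a mean chi-square when the input is real
#: human X data.  For unlinked simulated panels M_eff equals the SNP count.
M_EFF_HUMAN_X = 1300


@dataclass
class DCRResult:
    """DC-ratio estimate (male/female X-linked heritability ratio)."""

    gamma_hat: float
    se: float
    mean_chisq_m: float
    mean_chisq_f: float
    var_chisq_m: float
    var_chisq_f: float
    n_m: int
    n_f: int
    m_eff: float
    defined: bool = True


@dataclass
class RgResult:
    """Male-female genetic correlation with block-jackknife SE."""

    r_g_hat: float
    se: float
    cross_chisq: float
    mean_chisq_m: float
    mean_chisq_f: float
    n_blocks: int
    loo: np.ndarray = field(default_factory=lambda: np.array([]))
    defined: bool = True


@dataclass
class DCCResult:
    """Dosage compensation coefficient (weighted slope of beta_m on beta_f)."""

    dcc: float
    se: float
    n_loci: int
    discovery: str
    defined: bool = True


def mean_chisq(
    stats: SummaryStats,
    exclude_regions: Optional[Sequence[tuple]] = None,
    m_eff: Optional[float] = None,
) -> dict:
    """Mean chi-square over retained X non-PAR SNPs and its sampling variance.

    ``var(mean chisq) = (2 / M_eff) * [1 + 2 (mean chisq - 1)]``; ``m_eff``
    defaults to the retained SNP count (appropriate for unlinked panels).
    ``exclude_regions`` are closed (start_bp, end_bp) intervals.
    """
    t = stats.table
    keep = (t["chrom_class"] == X_NONPAR).to_numpy()
    if exclude_regions:
        bp = t["bp"].to_numpy()
        for lo, hi in exclude_regions:
            keep &= ~((bp >= lo) & (bp <= hi))
    if not keep.any():
        raise ValueError("no SNPs retained after masking")
    chisq = t.loc[keep, "chisq"].to_numpy()
    mean = float(chisq.mean())
    m_eff = float(len(chisq)) if m_eff is None else float(m_eff)
    var = (2.0 / m_eff) * (1.0 + 2.0 * (mean - 1.0))
    return {"mean": mean, "var": var, "m": int(keep.sum()), "m_eff": m_eff}


def estimate_dcr(
    mean_m: float,
    mean_f: float,
    n_m: int,
    n_f: int,
    m_eff: float,
) -> DCRResult:
    """DC ratio ``(mean_m - 1) N_f / ((mean_f - 1) N_m)`` with its SE.

    Flagged undefined (gamma/SE NaN) when either excess mean chi-square is
    non-positive: the estimator is meaningless without polygenic signal.
    """
    if not (np.isfinite(mean_m) and np.isfinite(mean_f)):
        raise ValueError("mean chi-squares must be finite")
    num, den = mean_m - 1.0, mean_f - 1.0
    var_m = (2.0 / m_eff) * (1.0 + 2.0 * num)
    var_f = (2.0 / m_eff) * (1.0 + 2.0 * den)
    if num <= 0 or den <= 0:
        return DCRResult(np.nan, np.nan, mean_m, mean_f, var_m, var_f,
                         n_m, n_f, m_eff, defined=False)
    gamma = (num * n_f) / (den * n_m)
    se = float(np.sqrt(gamma**2 * (var_m / num**2 + var_f / den**2)))
    return DCRResult(gamma, se, mean_m, mean_f, var_m, var_f, n_m, n_f, m_eff)


def dcr_from_stats(
    stats_m: SummaryStats,
    stats_f: SummaryStats,
    m_eff: Optional[float] = None,
    exclude_regions: Optional[Sequence[tuple]] = None,
) -> DCRResult:
    """Convenience wrapper: mean chi-squares from two strata, then the ratio."""
    mm = mean_chisq(stats_m, exclude_regions, m_eff)
    mf = mean_chisq(stats_f, exclude_regions, m_eff)
    n_m = int(stats_m.table["N"].iloc[0])
    n_f = int(stats_f.table["N"].iloc[0])
    return estimate_dcr(mm["mean"], mf["mean"], n_m, n_f, mm["m_eff"])


def _rg_point(zm: np.ndarray, zf: np.ndarray) -> float:
    cross = float(np.mean(zm * zf))
    num_m = float(np.mean(zm**2)) - 1.0
    num_f = float(np.mean(zf**2)) - 1.0
    prod = num_m * num_f
    if prod <= 0:
        return np.nan
    return cross / np.sqrt(prod)


def estimate_rg(
    stats_m: SummaryStats,
    stats_f: SummaryStats,
    B: int = 1000,
    exclude_regions: Optional[Sequence[tuple]] = None,
) -> RgResult:
    """Male-female genetic correlation from the Z-score cross-product.

    ``r_g = mean(z_m z_f) / sqrt((mean chisq_m - 1)(mean chisq_f - 1))``.
    The SE is a delete-one-block jackknife over ``B`` contiguous
    position-ordered blocks (B is capped at half the SNP count).
    """
    j = stats_m.aligned_with(stats_f)
    keep = (j["chrom_class_x"] == X_NONPAR).to_numpy()
    if exclude_regions:
        bp = j["bp_x"].to_numpy()
        for lo, hi in exclude_regions:
            keep &= ~((bp >= lo) & (bp <= hi))
    j = j[keep].sort_values("bp_x", kind="mergesort")
    m = len(j)
    if m < 4:
        raise ValueError("too few aligned SNPs for the genetic correlation")
    zm = j["z_x"].to_numpy()
    zf = j["z_y"].to_numpy()
    point = _rg_point(zm, zf)
    cross = float(np.mean(zm * zf))
    mcm, mcf = float(np.mean(zm**2)), float(np.mean(zf**2))
    B_used = int(min(B, m // 2))
    if B_used < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if not np.isfinite(point):
        return RgResult(np.nan, np.nan, cross, mcm, mcf, B_used, defined=False)
    blocks = np.array_split(np.arange(m), B_used)
    loo = np.empty(B_used)
    for k, blk in enumerate(blocks):
        mask = np.ones(m, dtype=bool)
        mask[blk] = False
        loo[k] = _rg_point(zm[mask], zf[mask])
    if not np.all(np.isfinite(loo)):
        return RgResult(point, np.nan, cross, mcm, mcf, B_used, loo, defined=False)
    se = float(np.sqrt((B_used - 1) / B_used * np.sum((point - loo) ** 2)))
    return RgResult(point, se, cross, mcm, mcf, B_used, loo)


def effect_size_ratio(beta_m: float, se_m: float, beta_f: float, se_f: float) -> dict:
    """Male/female per-allele effect ratio with its delta-method SE.

    ``SE^2 = ratio^2 (se_m^2/beta_m^2 + se_f^2/beta_f^2)``; undefined when
    beta_f is zero (and the SE additionally requires beta_m != 0).
    """
    if beta_f == 0:
        return {"ratio": np.nan, "se": np.nan, "defined": False}
    ratio = beta_m / beta_f
    if beta_m == 0:
        return {"ratio": ratio, "se": np.nan, "defined": False}
    se2 = ratio**2 * (se_m**2 / beta_m**2 + se_f**2 / beta_f**2)
    return {"ratio": float(ratio), "se": float(np.sqrt(se2)), "defined": True}


def estimate_dcc(
    pairs: pd.DataFrame,
    discovery: str = "COMBINED",
    weight_scheme: str = "male_var",
) -> DCCResult:
    """DCC: no-intercept weighted least squares of beta_m on beta_f.

    ``pairs`` needs columns beta_m, se_m, beta_f, se_f.  Weights are the
    inverse variance of the male-specific estimates (``male_var``); the
    ``both_var`` alternative adds the female-side variance to the weight
    denominator for sensitivity analyses.  The model ``beta_m = d beta_f``
    has no offset, so the regression is intercept-free.
    """
    pairs = pd.DataFrame(pairs)
    req = {"beta_m", "se_m", "beta_f", "se_f"}
    if not req <= set(pairs.columns):
        raise ValueError(f"pairs must have columns {sorted(req)}")
    if weight_scheme == "male_var":
        w = 1.0 / pairs["se_m"] ** 2
    elif weight_scheme == "both_var":
        w = 1.0 / (pairs["se_m"] ** 2 + pairs["se_f"] ** 2)
    else:
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    usable = np.isfinite(w) & (w > 0) & np.isfinite(pairs["beta_f"]) & np.isfinite(pairs["beta_m"])
    if usable.sum() < 2:
        raise ValueError("need at least 2 usable effect pairs for DCC")
    sub = pairs[usable]
    fit = sm.WLS(sub["beta_m"].to_numpy(), sub["beta_f"].to_numpy(),
                 weights=w[usable].to_numpy()).fit()
    return DCCResult(float(fit.params[0]), float(fit.bse[0]),
                     int(usable.sum()), discovery)


def h2_ratio(h2_m: float, se_m: float, h2_f: float, se_f: float) -> dict:
    """Male/female SNP-heritability ratio with its delta-method SE."""
    if h2_f <= 0:
        return {"ratio": np.nan, "se": np.nan, "defined": False}
    ratio = h2_m / h2_f
    if h2_m == 0:
        return {"ratio": 0.0, "se": np.nan, "defined": False}
    se2 = ratio**2 * (se_m**2 / h2_m**2 + se_f**2 / h2_f**2)
    return {"ratio": float(ratio), "se": float(np.sqrt(se2)), "defined": True}


def expected_dc(pi_escape: float) -> dict:
    """Analytic expectations under an escape fraction ``pi``.

    With equal female-side variance per locus, a fraction ``pi`` of loci at
    d=1 and the rest at d=2:

    * expected DC ratio  = 2 (1 - pi) + 0.5 pi   (per-locus variance ratios)
    * expected mean effect-size ratio = 2 (1 - pi) + 1 pi
    """
    if not 0 <= pi_escape <= 1:
        raise ValueError("pi_escape must lie in [0, 1]")
    return {
        "expected_dcr": 2.0 * (1 - pi_escape) + 0.5 * pi_escape,
        "expected_mean_ratio": 2.0 * (1 - pi_escape) + 1.0 * pi_escape,
    }
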