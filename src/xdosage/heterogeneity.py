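"""Male/female effect heterogeneity beyond dosage compensation.

Under full dosage compensation ``beta_m = 2 beta_f``, so
``T = (beta_m/2 - beta_f)^2 / (se_m^2/4 + se_f^2)`` is chi-square(1) under
the null of no heterogeneity.  Significant SNPs are grouped into LD-defined
regions (all partners with r^2 above a threshold to the top heterogeneity
SNP, padded and merged), and the DC ratio / genetic correlation can be
re-estimated with those regions masked out — male-specific (e.g. hormonally
driven) variance otherwise inflates the DC ratio past 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import SummaryStats, _ld_reference, _r2_to_index
from .dc_stats import DCRResult, RgResult, dcr_from_stats, estimate_dcr, estimate_rg, mean_chisq
from .simulate import GenotypeMatrix


@dataclass
class HetRegion:
    """A padded LD region around one top heterogeneity SNP.

    Internal coordinates are 1-based closed intervals.
    """

    top_snp: str
    chrom_class: str
    start: int
    end: int
    members: list
    pad: int
    min_p_het: float

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)


def het_test(beta_m, se_m, beta_f, se_f) -> pd.DataFrame:
    """Heterogeneity statistic and p-value (vectorised over SNPs)."""
    beta_m, se_m = np.atleast_1d(np.asarray(beta_m, float)), np.atleast_1d(np.asarray(se_m, float))
    beta_f, se_f = np.atleast_1d(np.asarray(beta_f, float)), np.atleast_1d(np.asarray(se_f, float))
    if np.any(se_m <= 0) or np.any(se_f <= 0):
        raise ValueError("standard errors must be positive")
    t_d = (0.5 * beta_m - beta_f) ** 2 / (0.25 * se_m**2 + se_f**2)
    return pd.DataFrame({"t_d": t_d, "p_het": sps.chi2.sf(t_d, df=1)})


def het_test_stats(stats_m: SummaryStats, stats_f: SummaryStats) -> pd.DataFrame:
    """Run the heterogeneity test across two aligned summary-statistic sets."""
    j = stats_m.aligned_with(stats_f)
    out = het_test(j["b_x"], j["se_x"], j["b_y"], j["se_y"])
    out.insert(0, "SNP", j["SNP"].to_numpy())
    out.insert(1, "chrom_class", j["chrom_class_x"].to_numpy())
    out.insert(2, "bp", j["bp_x"].to_numpy())
    return out


def define_het_regions(
    het: pd.DataFrame,
    G_ref: GenotypeMatrix,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.05,
    pad: int = 250_000,
    ref_sex: str = "pooled",
) -> list:
    """Greedy region formation around successive most-significant SNPs.

    Members are all SNPs with r^2 > ``r2_thresh`` to the top SNP, computed on
    the reference genotypes (pooled sexes under the {0,2} male coding by
    default; pass ``ref_sex='F'`` for a female-only reference).  The interval
    spans member positions +/- ``pad`` and overlapping padded regions are
    merged (the merged region keeps the more significant top SNP).
    """
    req = {"SNP", "bp", "p_het", "chrom_class"}
    if not req <= set(het.columns):
        raise ValueError(f"het table must have columns {sorted(req)}")
    G_ref = _ld_reference(G_ref, ref_sex)
    ref_ids = G_ref.variants["id"].to_numpy()
    ref_pos = {vid: i for i, vid in enumerate(ref_ids)}
    t = het[het["SNP"].isin(ref_ids)].copy()
    t["ref_idx"] = t["SNP"].map(ref_pos)
    t = t.sort_values(["p_het", "bp", "SNP"], kind="mergesort").reset_index(drop=True)
    alive = np.ones(len(t), dtype=bool)
    regions = []
    for i in range(len(t)):
        if not alive[i] or t["p_het"].iloc[i] >= p_thresh:
            continue
        others = np.flatnonzero(alive & (np.arange(len(t)) != i))
        members = [i]
        if len(others):
            r2 = _r2_to_index(G_ref, int(t["ref_idx"].iloc[i]),
                              t["ref_idx"].iloc[others].to_numpy())
            members += list(others[r2 > r2_thresh])
        bp = t["bp"].iloc[members]
        regions.append(
            HetRegion(
                top_snp=str(t["SNP"].iloc[i]),
                chrom_class=str(t["chrom_class"].iloc[i]),
                start=int(bp.min()) - pad,
                end=int(bp.max()) + pad,
                members=list(t["SNP"].iloc[members]),
                pad=pad,
                min_p_het=float(t["p_het"].iloc[i]),
            )
        )
        alive[members] = False
    return merge_regions(regions)


def merge_regions(regions: Sequence[HetRegion]) -> list:
    """Merge overlapping padded intervals, keeping the best top SNP."""
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: (r.chrom_class, r.start))
    merged = [regions[0]]
    for r in regions[1:]:
        last = merged[-1]
        if r.chrom_class == last.chrom_class and r.start <= last.end:
            best = last if last.min_p_het <= r.min_p_het else r
            merged[-1] = HetRegion(
                top_snp=best.top_snp,
                chrom_class=last.chrom_class,
                start=min(last.start, r.start),
                end=max(last.end, r.end),
                members=sorted(set(last.members) | set(r.members)),
                pad=last.pad,
                min_p_het=min(last.min_p_het, r.min_p_het),
            )
        else:
            merged.append(r)
    return merged


def regions_to_bed(regions: Sequence[HetRegion], path) -> None:
    """Write regions as BED (0-based half-open; internal 1-based closed)."""
    with open(path, "w") as fh:
        for r in regions:
            chrom = "X" if r.chrom_class.startswith("X") else "1"
            fh.write(f"{chrom}\t{max(r.start - 1, 0)}\t{r.end}\t{r.top_snp}\n")


def reestimate_excluding(
    stats_m: SummaryStats,
    stats_f: SummaryStats,
    regions: Sequence[HetRegion],
    n_m: Optional[int] = None,
    n_f: Optional[int] = None,
    m_eff: Optional[float] = None,
    m_eff_policy: str = "scale",
    B: int = 1000,
) -> dict:
    """DC ratio and genetic correlation before/after masking the regions.

    ``m_eff_policy='scale'`` shrinks M_eff by the retained-SNP fraction;
    ``'keep'`` passes the original M_eff through unchanged.
    """
    if m_eff_policy not in ("scale", "keep"):
        raise ValueError("m_eff_policy must be 'scale' or 'keep'")
    n_m = int(stats_m.table["N"].iloc[0]) if n_m is None else n_m
    n_f = int(stats_f.table["N"].iloc[0]) if n_f is None else n_f
    intervals = [r.interval for r in regions]

    before_m = mean_chisq(stats_m, None, m_eff)
    before_f = mean_chisq(stats_f, None, m_eff)
    # 'keep' reuses the pre-exclusion M_eff; 'scale' shrinks it by the
    # retained-SNP fraction
    after_m = mean_chisq(stats_m, intervals, before_m["m_eff"])  # raises if empty
    after_f = mean_chisq(stats_f, intervals, before_f["m_eff"])
    if m_eff_policy == "scale":
        for d, base in ((after_m, before_m), (after_f, before_f)):
            frac = d["m"] / base["m"]
            d["m_eff"] = base["m_eff"] * frac
            d["var"] = (2.0 / d["m_eff"]) * (1.0 + 2.0 * (d["mean"] - 1.0))
    dcr_before = estimate_dcr(before_m["mean"], before_f["mean"], n_m, n_f, before_m["m_eff"])
    dcr_after = estimate_dcr(after_m["mean"], after_f["mean"], n_m, n_f, after_m["m_eff"])
    rg_before = estimate_rg(stats_m, stats_f, B)
    rg_after = estimate_rg(stats_m, stats_f, B, exclude_regions=intervals)
    return {
        "dcr_before": dcr_before,
        "dcr_after": dcr_after,
        "rg_before": rg_before,
        "rg_after": rg_after,
    }
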