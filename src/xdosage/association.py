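"""Sex-stratified per-SNP association and lead-SNP selection.

The association engine is ordinary least squares: on unrelated simulated
individuals OLS is exact, and a covariate slot (e.g. principal components)
is available for real data.  Under diploid-style male coding ({0,2}) the
effect and standard error are rescaled by 2 so every reported estimate is
per-allele; test statistics are invariant to the coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import MALE_01, MALE_02, X_NONPAR, GenotypeMatrix

logger = logging.getLogger("xdosage")

MALE, FEMALE, COMBINED = "MALE", "FEMALE", "COMBINED"

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
EXT_COLUMNS = ["chrom_class", "bp", "stratum"]


@dataclass
class SummaryStats:
    """Per-SNP association results for one analysis stratum.

    ``table`` columns: SNP, A1, A2, freq, b, se, p, N plus extension columns
    chrom_class, bp, z, chisq.  ``b`` is the per-allele effect in trait SD
    units.
    """

    table: pd.DataFrame
    stratum: str

    def __post_init__(self) -> None:
        missing = [c for c in MA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")
        if "z" not in self.table.columns:
            self.table = self.table.assign(z=self.table["b"] / self.table["se"])
        if "chisq" not in self.table.columns:
            self.table = self.table.assign(chisq=self.table["z"] ** 2)

    def __len__(self) -> int:
        return len(self.table)

    def validate(self, rtol: float = 1e-10) -> None:
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("non-positive SE in summary statistics")
        np.testing.assert_allclose(t["chisq"], t["z"] ** 2, rtol=rtol)
        np.testing.assert_allclose(t["p"], sps.chi2.sf(t["chisq"], df=1), rtol=rtol)

    def aligned_with(self, other: "SummaryStats") -> pd.DataFrame:
        """Inner-join on SNP id with allele harmonisation (flip negates b)."""
        a = self.table.set_index("SNP")
        b = other.table.set_index("SNP")
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]
        same = (a["A1"] == b["A1"]) & (a["A2"] == b["A2"])
        flipped = (a["A1"] == b["A2"]) & (a["A2"] == b["A1"])
        drop = ~(same | flipped)
        if drop.any():
            logger.info("dropping %d unharmonisable SNPs", int(drop.sum()))
        b = b.copy()
        b.loc[flipped, "b"] *= -1
        b.loc[flipped, "z"] *= -1
        b.loc[flipped, "freq"] = 1 - b.loc[flipped, "freq"]
        keep = common[~drop.to_numpy()]
        out = a.loc[keep].join(b.loc[keep], lsuffix="_x", rsuffix="_y")
        return out.reset_index()


def _residualize(v: np.ndarray, covariates: Optional[np.ndarray]) -> np.ndarray:
    """Project out an intercept plus optional covariate columns."""
    r = v - v.mean(axis=0)
    if covariates is None:
        return r
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    C = C - C.mean(axis=0)
    coef, *_ = np.linalg.lstsq(C, r, rcond=None)
    return r - C @ coef


def run_xwas(
    G: GenotypeMatrix,
    y: np.ndarray,
    stratum: str,
    covariates: Optional[np.ndarray] = None,
    maf_min: float = 0.01,
) -> SummaryStats:
    """Per-SNP OLS of the (within-stratum standardised) trait on dosage.

    SNPs with within-stratum MAF <= ``maf_min`` or zero dosage variance are
    dropped and logged.  Effects are reported per allele regardless of male
    genotype coding.
    """
    y = np.asarray(y, dtype=float)
    if stratum == MALE:
        mask = G.is_male
    elif stratum == FEMALE:
        mask = G.is_female
    else:
        raise ValueError("stratum must be MALE or FEMALE")
    n = int(mask.sum())
    if n < 30:
        raise ValueError(f"stratum {stratum} has only {n} individuals (< 30)")
    X = G.dosages[mask]
    ys = y[mask]
    cov = None if covariates is None else np.asarray(covariates)[mask]
    n_cov = 0 if cov is None else (1 if cov.ndim == 1 else cov.shape[1])

    sex_label = "M" if stratum == MALE else "F"
    ploidy = G.ploidy(sex_label).astype(float)
    if G.coding == MALE_02 and stratum == MALE:
        hap = (G.variants["chrom_class"] == X_NONPAR).to_numpy()
        ploidy = np.where(hap, 2.0, ploidy)  # dosage 0/2 on a 2-copy scale
    sx = X.sum(axis=0, dtype=np.float64)
    sxx_all = np.einsum("ij,ij->j", X, X, dtype=np.float64) - sx**2 / n
    freq = sx / n / ploidy
    maf = np.minimum(freq, 1 - freq)
    keep = (maf > maf_min) & (sxx_all > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("run_xwas[%s]: dropped %d SNPs (MAF<=%.3g or zero variance)",
                    stratum, n_drop, maf_min)

    dof = n - 2 - n_cov
    if cov is None:
        # centred cross-moments without materialising centred copies
        yc = ys - ys.mean()
        sxx = sxx_all[keep]
        sxy = (X[:, keep].T @ yc.astype(X.dtype)).astype(np.float64)
        syy = float(yc @ yc)
    else:
        Xr = _residualize(np.asarray(X[:, keep], dtype=np.float64), cov)
        yr = _residualize(ys, cov)
        sxx = np.einsum("ij,ij->j", Xr, Xr)
        sxy = Xr.T @ yr
        syy = float(yr @ yr)
    b = sxy / sxx
    rss = syy - b * sxy
    se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx)

    # rescale diploid-coded male X results to the per-allele scale
    if G.coding == MALE_02 and stratum == MALE:
        hapk = (G.variants["chrom_class"] == X_NONPAR).to_numpy()[keep]
        b = np.where(hapk, 2 * b, b)
        se = np.where(hapk, 2 * se, se)

    z = b / se
    chisq = z**2
    var = G.variants.loc[keep]
    table = pd.DataFrame(
        {
            "SNP": var["id"].to_numpy(),
            "A1": var["a1"].to_numpy(),
            "A2": var["a2"].to_numpy(),
            "freq": freq[keep],
            "b": b,
            "se": se,
            "p": sps.chi2.sf(chisq, df=1),
            "N": n,
            "chrom_class": var["chrom_class"].to_numpy(),
            "bp": var["bp"].to_numpy(),
            "z": z,
            "chisq": chisq,
        }
    )
    return SummaryStats(table, stratum)


def meta_analyse(stats_m: SummaryStats, stats_f: SummaryStats) -> SummaryStats:
    """Inverse-variance-weighted fixed-effect meta-analysis of the two sexes."""
    j = stats_m.aligned_with(stats_f)
    w_m, w_f = 1 / j["se_x"] ** 2, 1 / j["se_y"] ** 2
    b = (j["b_x"] * w_m + j["b_y"] * w_f) / (w_m + w_f)
    se = np.sqrt(1 / (w_m + w_f))
    z = b / se
    n = j["N_x"] + j["N_y"]
    freq = (j["freq_x"] * j["N_x"] + j["freq_y"] * j["N_y"]) / n
    table = pd.DataFrame(
        {
            "SNP": j["SNP"],
            "A1": j["A1_x"],
            "A2": j["A2_x"],
            "freq": freq,
            "b": b,
            "se": se,
            "p": sps.chi2.sf(z**2, df=1),
            "N": n,
            "chrom_class": j["chrom_class_x"],
            "bp": j["bp_x"],
            "z": z,
            "chisq": z**2,
        }
    )
    return SummaryStats(table, COMBINED)


def gxs_test(
    G: GenotypeMatrix,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Genotype-by-sex interaction model ``y ~ g + sex + g:sex`` per SNP.

    Returns the 2-df joint Wald test of (g, g:sex), the 1-df interaction
    test, and the per-sex slopes implied by the fit.  Mean sex differences
    are absorbed by the sex main effect.
    """
    y = np.asarray(y, dtype=float)
    males = G.is_male
    if males.all() or (~males).all():
        raise ValueError("gxs_test requires both sexes")
    s = males.astype(float)
    n = G.n
    cov = None
    n_cov = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        n_cov = cov.shape[1]
    rows = []
    for jdx in range(G.m):
        g = G.dosages[:, jdx]
        cols = [np.ones(n), g, s, g * s]
        if cov is not None:
            cols.extend(cov.T)
        X = np.column_stack(cols)
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            continue
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - X.shape[1])
        V = XtX_inv * sigma2
        sub = [1, 3]  # (g, g:sex)
        stat_joint = float(beta[sub] @ np.linalg.solve(V[np.ix_(sub, sub)], beta[sub]))
        stat_gxs = float(beta[3] ** 2 / V[3, 3])
        rows.append(
            {
                "SNP": G.variants["id"].iloc[jdx],
                "beta_f": beta[1],
                "beta_m": beta[1] + beta[3],
                "beta_gxs": beta[3],
                "stat_joint": stat_joint,
                "p_joint": float(sps.chi2.sf(stat_joint, df=2)),
                "stat_gxs": stat_gxs,
                "p_gxs": float(sps.chi2.sf(stat_gxs, df=1)),
            }
        )
    return pd.DataFrame(rows)


def sex_diff_expression(
    expr: np.ndarray,
    sex: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> dict:
    """Wald test of a fixed sex effect on expression (female-minus-male shift)."""
    expr = np.asarray(expr, dtype=float)
    sex = np.asarray(sex)
    if (sex == "M").all() or (sex == "F").all():
        raise ValueError("sex_diff_expression requires both sexes")
    if np.ptp(expr) == 0:
        raise ValueError("constant expression vector")
    female = (sex == "F").astype(float)
    cols = [np.ones(len(expr)), female]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        cols.extend(C.T if C.ndim == 2 else [C])
    X = np.column_stack(cols)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ expr)
    resid = expr - X @ beta
    sigma2 = resid @ resid / (len(expr) - X.shape[1])
    se = float(np.sqrt(XtX_inv[1, 1] * sigma2))
    wald = (beta[1] / se) ** 2
    return {
        "estimate": float(beta[1]),
        "se": se,
        "wald": float(wald),
        "p": float(sps.chi2.sf(wald, df=1)),
    }


# ---------------------------------------------------------------------------
# lead-SNP selection
# ---------------------------------------------------------------------------

@dataclass
class LeadSNPSet:
    """Clumped lead SNPs with the parameters that produced them."""

    table: pd.DataFrame  # SNP, bp, p, stratum (+ optional b/se columns)
    p_thresh: float
    r2_thresh: float
    window_bp: int
    stratum: str = field(default="")

    def __len__(self) -> int:
        return len(self.table)

    def with_sex_effects(self, stats_m: "SummaryStats",
                         stats_f: "SummaryStats") -> pd.DataFrame:
        """Annotate each lead SNP with the per-sex effect estimates."""
        j = stats_m.aligned_with(stats_f).set_index("SNP")
        keep = self.table[self.table["SNP"].isin(j.index)]
        sub = j.loc[keep["SNP"]]
        return pd.DataFrame({
            "SNP": keep["SNP"].to_numpy(),
            "stratum": keep["stratum"].to_numpy(),
            "p": keep["p"].to_numpy(),
            "beta_m": sub["b_x"].to_numpy(),
            "se_m": sub["se_x"].to_numpy(),
            "beta_f": sub["b_y"].to_numpy(),
            "se_f": sub["se_y"].to_numpy(),
        })


def _ld_reference(G_ref: GenotypeMatrix, ref_sex: str = "pooled") -> GenotypeMatrix:
    """Prepare genotypes for r^2: single-sex subset, or pooled sexes under
    the {0,2} male coding (equal sex means, so no spurious cross-SNP
    correlation from the male/female dosage-scale difference)."""
    if ref_sex in ("M", "F"):
        return G_ref.subset(individuals=np.flatnonzero(G_ref.sex == ref_sex))
    return G_ref.recode(MALE_02)


def _r2_to_index(G_ref: GenotypeMatrix, idx: int, others: np.ndarray) -> np.ndarray:
    x = G_ref.dosages[:, idx]
    Y = G_ref.dosages[:, others]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * np.einsum("ij,ij->j", Yc, Yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Yc.T @ xc) / denom, 0.0)
    return r**2


def clump_lead_snps(
    stats: SummaryStats,
    G_ref: GenotypeMatrix,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.05,
    window_bp: int = 50_000_000,
    ref_sex: str = "pooled",
) -> LeadSNPSet:
    """Greedy LD clumping: repeatedly take the most significant SNP below
    ``p_thresh`` and remove its LD partners (r^2 > ``r2_thresh`` within
    ``window_bp``).  Ties break on smaller p, then smaller position, then id.
    """
    G_ref = _ld_reference(G_ref, ref_sex)
    ref_ids = G_ref.variants["id"].to_numpy()
    t = stats.table[stats.table["SNP"].isin(ref_ids)].copy()
    if t.empty:
        raise ValueError("no overlap between summary statistics and LD reference")
    ref_pos = {vid: i for i, vid in enumerate(ref_ids)}
    t["ref_idx"] = t["SNP"].map(ref_pos)
    t = t.sort_values(["p", "bp", "SNP"], kind="mergesort").reset_index(drop=True)
    alive = np.ones(len(t), dtype=bool)
    leads = []
    bp = t["bp"].to_numpy()
    for i in range(len(t)):
        if not alive[i] or t["p"].iloc[i] >= p_thresh:
            continue
        leads.append(i)
        near = alive & (np.abs(bp - bp[i]) <= window_bp)
        near[i] = False
        cand = np.flatnonzero(near)
        if len(cand):
            r2 = _r2_to_index(G_ref, int(t["ref_idx"].iloc[i]),
                              t["ref_idx"].iloc[cand].to_numpy())
            alive[cand[r2 > r2_thresh]] = False
        alive[i] = False
    out = t.iloc[leads][["SNP", "bp", "p", "b", "se", "freq"]].reset_index(drop=True)
    out["stratum"] = stats.stratum
    return LeadSNPSet(out, p_thresh, r2_thresh, window_bp, stats.stratum)


def top_eqtl(
    stats: SummaryStats,
    n_traits: int,
    n_snps: int,
    alpha: float = 0.05,
) -> Optional[pd.Series]:
    """Best SNP for one expression trait iff it clears the Bonferroni
    threshold ``alpha / (n_traits * n_snps)``; ties break on position then id."""
    thresh = alpha / (n_traits * n_snps)
    t = stats.table.sort_values(["p", "bp", "SNP"], kind="mergesort")
    if t.empty or t["p"].iloc[0] >= thresh:
        return None
    return t.iloc[0]
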