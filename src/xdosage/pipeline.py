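"""End-to-end experiment orchestration and summary-statistic file I/O.

Composes simulate -> sex-stratified XWAS -> meta-analysis -> lead-SNP
selection -> DC estimators (+ heterogeneity regions, optional REML), with
one global seed expanded into per-stage child seeds so stages can be re-run
independently, and a structured log of every filter's in/out counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (COMBINED, FEMALE, MALE, MA_COLUMNS, SummaryStats,
                          clump_lead_snps, meta_analyse, run_xwas)
from .dc_stats import DCCResult, DCRResult, RgResult, dcr_from_stats, estimate_dcc, estimate_rg
from .greml import compute_grm, reml_fit
from .heterogeneity import define_het_regions, het_test_stats, reestimate_excluding
from .simulate import SimConfig, SimData, simulate_dataset

logger = logging.getLogger("xdosage")

MALE_DISC, FEMALE_DISC, COMBINED_DISC = "MALE_DISC", "FEMALE_DISC", "COMBINED_DISC"
SCHEMES = (MALE_DISC, FEMALE_DISC, COMBINED_DISC)


def stage_seed(seed: int, stage: int) -> np.random.SeedSequence:
    """Counter-based child seed: independent streams per pipeline stage."""
    return np.random.SeedSequence([int(seed), int(stage)])


# ---------------------------------------------------------------------------
# summary-statistic files (.ma dialect: SNP A1 A2 freq b se p N)
# ---------------------------------------------------------------------------

def write_sumstats(stats: SummaryStats, path) -> None:
    """Write a `.ma`-dialect file (mandatory columns first, extensions after)."""
    t = stats.table.copy()
    t["stratum"] = stats.stratum
    extras = [c for c in t.columns if c not in MA_COLUMNS]
    t[MA_COLUMNS + extras].to_csv(path, sep="\t", index=False)


def load_sumstats(path, stratum: Optional[str] = None) -> SummaryStats:
    """Read a `.ma`-dialect file; unknown columns are preserved.

    Missing mandatory columns are rejected by name; rows with unparseable
    mandatory fields are reported with 1-based data line numbers.
    """
    t = pd.read_csv(path, sep="\t")
    missing = [c for c in MA_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    numeric = ["freq", "b", "se", "p", "N"]
    coerced = t[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1) & t[numeric].notna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad)]  # +1 header +1 one-based
        raise ValueError(f"{path}: malformed rows at line(s) {lines[:20]}")
    t[numeric] = coerced
    if t[numeric].isna().any().any():
        lines = [int(i) + 2 for i in np.flatnonzero(t[numeric].isna().any(axis=1))]
        raise ValueError(f"{path}: missing values at line(s) {lines[:20]}")
    if stratum is None:
        stratum = str(t["stratum"].iloc[0]) if "stratum" in t.columns else "UNKNOWN"
    if "chrom_class" not in t.columns:
        t["chrom_class"] = "X_NONPAR"
    if "bp" not in t.columns:
        t["bp"] = np.arange(1, len(t) + 1)
    return SummaryStats(t, stratum)


# ---------------------------------------------------------------------------
# discovery / replication designs
# ---------------------------------------------------------------------------

def discovery_replication(
    stats_m: SummaryStats,
    stats_f: SummaryStats,
    scheme: str = COMBINED_DISC,
    p_thresh: float = 5e-8,
    stats_c: Optional[SummaryStats] = None,
) -> DCCResult:
    """DCC under a discovery-sex design.

    Loci are selected by ``p < p_thresh`` in the discovery stratum (the
    inverse-variance meta-analysis for COMBINED_DISC), effect pairs are
    extracted from *both* sex-stratified analyses, and the DCC slope is
    fitted.  Selecting and estimating in the same sex exposes winner's-curse
    bias: male discovery inflates the slope, female discovery deflates it.
    Returns an empty-result flag (n_loci = 0) when nothing is selected.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if scheme == COMBINED_DISC:
        disc = stats_c if stats_c is not None else meta_analyse(stats_m, stats_f)
    else:
        disc = stats_m if scheme == MALE_DISC else stats_f
    sel = disc.table.loc[disc.table["p"] < p_thresh, "SNP"]
    j = stats_m.aligned_with(stats_f)
    j = j[j["SNP"].isin(sel)]
    if len(j) < 2:
        return DCCResult(np.nan, np.nan, len(j), scheme, defined=False)
    pairs = pd.DataFrame(
        {"beta_m": j["b_x"], "se_m": j["se_x"], "beta_f": j["b_y"], "se_f": j["se_y"]}
    )
    return estimate_dcc(pairs, discovery=scheme)


def downsample_stratum(
    G_n: int,
    stratum_mask: np.ndarray,
    target_n: int,
    replicates: int,
    seed: int = 0,
) -> list:
    """Without-replacement subsample index sets for one stratum.

    Returns ``replicates`` arrays of individual indices in which the chosen
    stratum is reduced to ``target_n`` and everyone else is kept, for
    re-running any downstream analysis per replicate.
    """
    stratum_idx = np.flatnonzero(stratum_mask)
    other_idx = np.flatnonzero(~stratum_mask)
    if target_n > len(stratum_idx):
        raise ValueError(f"target_n {target_n} exceeds stratum size {len(stratum_idx)}")
    out = []
    for r in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        pick = np.sort(rng.choice(stratum_idx, size=target_n, replace=False))
        out.append(np.sort(np.concatenate([pick, other_idx])))
    return out


# ---------------------------------------------------------------------------
# experiment configuration and report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    p_thresh: float = 5e-8
    r2_thresh: float = 0.05
    window_bp: int = 50_000_000
    het_p_thresh: float = 5e-8
    het_pad: int = 250_000
    jackknife_blocks: int = 1000
    m_eff: Optional[float] = None        # None -> SNP count (unlinked panel)
    m_eff_policy: str = "scale"
    maf_min: float = 0.01
    do_greml: bool = False
    greml_n_per_sex: int = 1000
    dcc_schemes: tuple = SCHEMES


@dataclass
class ExperimentReport:
    """All numeric results of one experiment plus provenance."""

    config: dict
    seed: int
    dcr: DCRResult
    rg: RgResult
    dcc: dict                        # scheme -> DCCResult
    het_regions: list
    dcr_after_exclusion: Optional[DCRResult] = None
    rg_after_exclusion: Optional[RgResult] = None
    greml: Optional[dict] = None     # 'M'/'F' -> VarianceComponents
    files: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path) -> None:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"cannot encode {type(o)}")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=enc)


def _validate_config(raw: dict) -> tuple:
    errors = []
    sim_raw = raw.get("sim", {})
    ana_raw = raw.get("analysis", {})
    known_top = {"sim", "analysis", "seed"}
    for key in set(raw) - known_top:
        errors.append(f"unknown top-level field '{key}'")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for key in set(sim_raw) - sim_fields:
        errors.append(f"unknown field 'sim.{key}'")
    ana_fields = {f.name for f in dataclasses.fields(AnalysisConfig)}
    for key in set(ana_raw) - ana_fields:
        errors.append(f"unknown field 'analysis.{key}'")
    if errors:
        raise ValueError("config errors: " + "; ".join(errors))
    if "maf_range" in sim_raw:
        sim_raw = {**sim_raw, "maf_range": tuple(sim_raw["maf_range"])}
    try:
        sim = SimConfig(**sim_raw)
    except ValueError as e:
        raise ValueError(f"config error under 'sim': {e}") from None
    ana = AnalysisConfig(**ana_raw)
    return sim, ana


def run_experiment(config: dict, seed: Optional[int] = None, outdir=None) -> ExperimentReport:
    """Simulate -> associate -> estimate -> report.

    ``config`` has sections ``sim`` (mirrors SimConfig), ``analysis``
    (thresholds, M_eff policy, optional REML) and ``seed``.  Identical config
    and seed reproduce every numeric field bit-identically.
    """
    sim_cfg, ana = _validate_config(dict(config))
    seed = int(config.get("seed", sim_cfg.seed)) if seed is None else int(seed)

    data: SimData = simulate_dataset(sim_cfg, seed=seed)
    G, phen = data.genotypes, data.phenotypes
    stats_m = run_xwas(G, phen.y_std, MALE, maf_min=ana.maf_min)
    stats_f = run_xwas(G, phen.y_std, FEMALE, maf_min=ana.maf_min)
    stats_c = meta_analyse(stats_m, stats_f)
    logger.info("xwas: %d male / %d female / %d combined SNPs",
                len(stats_m), len(stats_f), len(stats_c))

    dcr = dcr_from_stats(stats_m, stats_f, m_eff=ana.m_eff)
    rg = estimate_rg(stats_m, stats_f, B=ana.jackknife_blocks)
    dcc = {
        scheme: discovery_replication(stats_m, stats_f, scheme,
                                      ana.p_thresh, stats_c=stats_c)
        for scheme in ana.dcc_schemes
    }

    het = het_test_stats(stats_m, stats_f)
    regions = define_het_regions(het, G, ana.het_p_thresh, ana.r2_thresh, ana.het_pad)
    dcr_after = rg_after = None
    if regions:
        re = reestimate_excluding(stats_m, stats_f, regions, m_eff=ana.m_eff,
                                  m_eff_policy=ana.m_eff_policy,
                                  B=ana.jackknife_blocks)
        dcr_after, rg_after = re["dcr_after"], re["rg_after"]

    greml_res = None
    if ana.do_greml and data.background is not None:
        greml_res = {}
        rng = np.random.default_rng(stage_seed(seed, 901))
        for label in ("M", "F"):
            idx = np.flatnonzero(G.sex == label)
            if len(idx) > ana.greml_n_per_sex:
                idx = np.sort(rng.choice(idx, ana.greml_n_per_sex, replace=False))
            Gs = G.subset(individuals=idx)
            Bs = data.background.subset(individuals=idx)
            a_x = compute_grm(Gs)
            a_g = compute_grm(Bs)
            greml_res[label] = reml_fit(
                phen.y[idx], [a_g, a_x], names=["sigma2_G", "sigma2_X", "sigma2_e"])

    files = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, st in (("male", stats_m), ("female", stats_f), ("combined", stats_c)):
            path = outdir / f"sumstats_{name}.ma"
            write_sumstats(st, path)
            files[name] = str(path)
        het.to_csv(outdir / "het_test.tsv", sep="\t", index=False)
        files["het"] = str(outdir / "het_test.tsv")

    cfg_echo = {"sim": dataclasses.asdict(sim_cfg),
                "analysis": dataclasses.asdict(ana), "seed": seed}
    cfg_echo["sim"]["maf_range"] = list(cfg_echo["sim"]["maf_range"])
    report = ExperimentReport(
        config=cfg_echo, seed=seed, dcr=dcr, rg=rg, dcc=dcc,
        het_regions=regions, dcr_after_exclusion=dcr_after,
        rg_after_exclusion=rg_after, greml=greml_res, files=files,
    )
    if outdir is not None:
        report.to_json(outdir / "report.json")
    return report


def load_experiment_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
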