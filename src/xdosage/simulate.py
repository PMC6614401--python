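"""Simulation of X-linked trait architectures under arbitrary X-inactivation states.

Generates haploid-male / diploid-female X genotypes, per-locus dosage-
compensation states ``d`` (``d = 2`` full compensation, ``d = 1`` escape),
effect sizes with ``beta_m = d * beta_f + delta``, polygenic phenotypes and
single-eQTL expression traits.  Everything is driven by an explicit seed and
reproduces bit-identically.

Genetic-variance bookkeeping
----------------------------
For a locus with allele frequency ``p`` and female per-allele effect
``beta_f`` the female genetic variance is ``2 p (1-p) beta_f**2`` (diploid)
and the male variance is ``p (1-p) beta_m**2`` (haploid), so the male/female
variance ratio at a single locus is ``d**2 / 2``: 2 under full dosage
compensation, 0.5 under complete escape.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

AUTOSOME = "AUTOSOME"
X_NONPAR = "X_NONPAR"
X_PAR = "X_PAR"
CHROM_CLASSES = (AUTOSOME, X_NONPAR, X_PAR)

MALE_01 = "MALE_01"  # male X non-PAR dosages in {0, 1} (per-allele scale)
MALE_02 = "MALE_02"  # male X non-PAR dosages in {0, 2} (diploid-style coding)

_CHROM_LABEL = {AUTOSOME: "1", X_NONPAR: "X", X_PAR: "X"}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# variant / genotype containers
# ---------------------------------------------------------------------------

def make_variants(
    freqs: np.ndarray,
    chrom_class: str = X_NONPAR,
    start_bp: int = 1,
    spacing_bp: int = 1_000,
    prefix: str = "snp",
) -> pd.DataFrame:
    """Build a variant table (id, chrom_class, bp, a1, a2, freq).

    Positions are 1-based and strictly increasing within the chromosome
    class.  ``freq`` is the allele-1 frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    if chrom_class not in CHROM_CLASSES:
        raise ValueError(f"unknown chrom_class {chrom_class!r}")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("monomorphic variants (freq 0 or 1) are not allowed")
    m = len(freqs)
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i}" for i in range(m)],
            "chrom_class": chrom_class,
            "bp": start_bp + spacing_bp * np.arange(m, dtype=np.int64),
            "a1": "A",
            "a2": "G",
            "freq": freqs,
        }
    )


@dataclass
class GenotypeMatrix:
    """Allele-1 dosages (individuals x variants) with sex and variant metadata.

    Female X non-PAR dosages are in {0,1,2}; male dosages are in {0,1} under
    ``MALE_01`` and {0,2} under ``MALE_02``.  PAR and autosomal dosages are
    diploid in both sexes.
    """

    variants: pd.DataFrame
    sex: np.ndarray            # array of 'M'/'F', length n
    dosages: np.ndarray        # (n, m) float
    coding: str = MALE_01

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex)
        self.dosages = np.asarray(self.dosages)
        if not np.issubdtype(self.dosages.dtype, np.floating):
            # float32 is exact for dosage values and halves memory traffic
            self.dosages = self.dosages.astype(np.float32)
        if self.dosages.shape != (len(self.sex), len(self.variants)):
            raise ValueError("dosage matrix shape does not match sex/variants")
        if self.coding not in (MALE_01, MALE_02):
            raise ValueError(f"unknown coding {self.coding!r}")

    @property
    def n(self) -> int:
        return len(self.sex)

    @property
    def m(self) -> int:
        return len(self.variants)

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == "M"

    @property
    def is_female(self) -> np.ndarray:
        return self.sex == "F"

    def ploidy(self, stratum: str) -> np.ndarray:
        """Per-variant chromosome copy number for one sex stratum."""
        hap = (self.variants["chrom_class"] == X_NONPAR).to_numpy()
        if stratum == "M":
            return np.where(hap, 1, 2)
        return np.full(self.m, 2)

    def recode(self, coding: str) -> "GenotypeMatrix":
        """Return a copy under the requested male X non-PAR coding."""
        if coding == self.coding:
            return self
        dos = self.dosages.copy()
        xmask = (self.variants["chrom_class"] == X_NONPAR).to_numpy()
        males = self.is_male
        scale = 2.0 if coding == MALE_02 else 0.5
        dos[np.ix_(males, xmask)] *= scale
        return GenotypeMatrix(self.variants, self.sex.copy(), dos, coding)

    def subset(self, individuals=None, variants=None) -> "GenotypeMatrix":
        ind = np.arange(self.n) if individuals is None else np.asarray(individuals)
        var = np.arange(self.m) if variants is None else np.asarray(variants)
        return GenotypeMatrix(
            self.variants.iloc[var].reset_index(drop=True),
            self.sex[ind],
            self.dosages[np.ix_(ind, var)],
            self.coding,
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def draw_allele_frequencies(m: int, maf_range=(0.01, 0.5), seed=0) -> np.ndarray:
    """Draw ``m`` allele frequencies uniform on ``maf_range`` (MAF scale).

    Each returned frequency ``p`` satisfies ``min(p, 1-p) >= maf_low``; with
    probability one half the frequency is reflected to ``1-p`` so that allele
    1 is not always the minor allele.
    """
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"invalid MAF range ({lo}, {hi}): need 0 < low <= high <= 0.5")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=m)
    flip = rng.random(m) < 0.5
    p[flip] = 1.0 - p[flip]
    return p


def simulate_genotypes(
    freqs: np.ndarray,
    n_m: int,
    n_f: int,
    chrom_class: str = X_NONPAR,
    seed=0,
    ld_blocks: Optional[Sequence[dict]] = None,
    start_bp: int = 1,
    spacing_bp: int = 1_000,
    prefix: str = "snp",
) -> GenotypeMatrix:
    """Simulate unlinked genotypes: one Bernoulli(p) draw per male X non-PAR
    haplotype, two independent draws per female (and per anybody on PAR or
    autosomes).

    ``ld_blocks`` optionally introduces local LD: each entry
    ``{"start": i, "end": j, "rho": r}`` (variant-index half-open range)
    draws haplotypes from an equicorrelated Gaussian copula with latent
    correlation ``r`` inside the block.
    """
    freqs = np.asarray(freqs, dtype=float)
    if n_m < 1 or n_f < 1:
        raise ValueError("sample sizes must be >= 1")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    rng = _rng(seed)
    m = len(freqs)
    variants = make_variants(freqs, chrom_class, start_bp, spacing_bp, prefix)
    male_haploid = chrom_class == X_NONPAR

    f32 = freqs.astype(np.float32)

    def draw_haplotypes(n_hap: int) -> np.ndarray:
        if not ld_blocks:
            return (rng.random((n_hap, m), dtype=np.float32) < f32).astype(np.float32)
        thresh = sps.norm.ppf(freqs)
        z = rng.standard_normal((n_hap, m))
        for blk in ld_blocks:
            i, j, rho = int(blk["start"]), int(blk["end"]), float(blk["rho"])
            if not (0 <= rho < 1):
                raise ValueError("block rho must be in [0, 1)")
            shared = rng.standard_normal(n_hap)[:, None]
            z[:, i:j] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z[:, i:j]
        return (z < thresh).astype(np.float32)

    male = draw_haplotypes(n_m) if male_haploid else draw_haplotypes(n_m) + draw_haplotypes(n_m)
    female = draw_haplotypes(n_f) + draw_haplotypes(n_f)
    dosages = np.vstack([male, female])
    sex = np.array(["M"] * n_m + ["F"] * n_f)
    return GenotypeMatrix(variants, sex, dosages, MALE_01)


def assign_dc_model(m_causal: int, pi_escape: float, d_values=None, seed=0) -> np.ndarray:
    """Per-locus dosage-compensation states for the causal loci.

    ``round(pi_escape * m_causal)`` loci get ``d = 1`` (escape) at shuffled
    positions; the remainder get ``d = 2`` (full compensation).  An explicit
    ``d_values`` array (values in [1, 2], e.g. for "variable" escape)
    overrides the two-state mixture.
    """
    if not 0 <= pi_escape <= 1:
        raise ValueError("pi_escape must lie in [0, 1]")
    if d_values is not None:
        d = np.asarray(d_values, dtype=float)
        if len(d) != m_causal:
            raise ValueError("d_values length must equal m_causal")
        if np.any((d < 1) | (d > 2)):
            raise ValueError("d values must lie in [1, 2]")
        return d.copy()
    n_escape = int(round(pi_escape * m_causal))
    d = np.full(m_causal, 2.0)
    idx = _rng(seed).permutation(m_causal)[:n_escape]
    d[idx] = 1.0
    return d


@dataclass
class EffectSet:
    """Per-locus effects over a variant panel.

    ``beta_f`` is the female per-allele effect (trait SD units per allele),
    ``d`` the dosage-compensation state, ``delta_m`` a male-specific additive
    deviation.  The male per-allele effect is always
    ``beta_m = d * beta_f + delta_m``.
    """

    beta_f: np.ndarray
    d: np.ndarray
    delta_m: np.ndarray
    causal_idx: np.ndarray

    @property
    def beta_m(self) -> np.ndarray:
        return self.d * self.beta_f + self.delta_m

    def genetic_variance(self, freqs: np.ndarray, stratum: str) -> float:
        """Expected X-linked genetic variance in one sex (haploid males)."""
        p = np.asarray(freqs)
        if stratum == "M":
            return float(np.sum(p * (1 - p) * self.beta_m**2))
        return float(np.sum(2 * p * (1 - p) * self.beta_f**2))

    def to_frame(self, variants: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": variants["id"].to_numpy(),
                "bp": variants["bp"].to_numpy(),
                "beta_f": self.beta_f,
                "beta_m": self.beta_m,
                "d": self.d,
                "delta_m": self.delta_m,
                "causal": np.isin(np.arange(len(self.beta_f)), self.causal_idx),
            }
        )


def draw_effects(
    freqs: np.ndarray,
    d_causal: np.ndarray,
    m_causal: int,
    h2x_f: float,
    equal_var_per_locus: bool = True,
    het_regions: Optional[Sequence[dict]] = None,
    seed=0,
    positions: Optional[np.ndarray] = None,
) -> EffectSet:
    """Draw per-locus effects with female X-linked heritability ``h2x_f``.

    Female effects are scaled so that ``sum(2 p (1-p) beta_f**2)`` over the
    causal loci equals ``h2x_f`` exactly (female phenotypic variance is
    normalised to 1).  With ``equal_var_per_locus`` each causal locus
    contributes the same female-side variance (``|beta_f|`` proportional to
    ``[2p(1-p)]**-0.5`` with random signs); otherwise effects are Gaussian
    before rescaling.

    ``het_regions`` entries ``{"start": lo, "end": hi, "delta_sd": s}``
    (closed base-pair intervals when ``positions`` is given, else variant
    index ranges) add male-specific deviations ``delta ~ N(0, s**2)`` at
    every locus inside the interval.
    """
    freqs = np.asarray(freqs, dtype=float)
    m = len(freqs)
    if m_causal > m:
        raise ValueError("m_causal exceeds number of loci")
    if m_causal > 0 and h2x_f <= 0:
        raise ValueError("h2x_f must be > 0 when causal loci are requested")
    d_causal = np.asarray(d_causal, dtype=float)
    if len(d_causal) != m_causal:
        raise ValueError("d_causal length must equal m_causal")
    rng = _rng(seed)

    causal_idx = np.sort(rng.permutation(m)[:m_causal])
    beta_f = np.zeros(m)
    d = np.full(m, 2.0)
    d[causal_idx] = d_causal
    if m_causal > 0:
        het_var = 2 * freqs[causal_idx] * (1 - freqs[causal_idx])
        if equal_var_per_locus:
            raw = rng.choice([-1.0, 1.0], size=m_causal) / np.sqrt(het_var)
        else:
            raw = rng.standard_normal(m_causal)
        scale = np.sqrt(h2x_f / np.sum(het_var * raw**2))
        beta_f[causal_idx] = raw * scale

    delta = np.zeros(m)
    if het_regions:
        coord = np.asarray(positions) if positions is not None else np.arange(m)
        for reg in het_regions:
            inside = (coord >= reg["start"]) & (coord <= reg["end"])
            delta[inside] = rng.normal(0.0, float(reg["delta_sd"]), size=int(inside.sum()))
    return EffectSet(beta_f=beta_f, d=d, delta_m=delta, causal_idx=causal_idx)


@dataclass
class Phenotypes:
    """Raw and within-sex standardised trait values plus variance bookkeeping."""

    y: np.ndarray
    y_std: np.ndarray
    sex: np.ndarray
    var_gx: dict
    var_bg: float
    var_resid: dict


def simulate_phenotypes(
    G: GenotypeMatrix,
    E: EffectSet,
    h2_bg: float = 0.0,
    seed=0,
    background: Optional[GenotypeMatrix] = None,
) -> Phenotypes:
    """Phenotypes ``y = X beta_sex + g_bg + e`` with unit total variance per sex.

    The background genetic term is either a Normal polygenic value of
    variance ``h2_bg`` (default) or, when ``background`` autosomal genotypes
    are supplied, an explicit genetic value from Gaussian per-allele effects
    scaled to ``h2_bg``.  Residual variance is set per sex so the expected
    total variance is 1 in each sex; negative implied residual variance is
    rejected.
    """
    if len(E.beta_f) != G.m:
        raise ValueError("effect set does not match the genotype panel")
    if G.coding != MALE_01:
        G = G.recode(MALE_01)
    rng = _rng(seed)
    n = G.n
    males = G.is_male
    p = G.variants["freq"].to_numpy()
    var_gx = {"M": E.genetic_variance(p, "M"), "F": E.genetic_variance(p, "F")}

    bm = E.beta_m.astype(G.dosages.dtype)
    bf = E.beta_f.astype(G.dosages.dtype)
    g_x = np.where(males, G.dosages @ bm, G.dosages @ bf).astype(np.float64)

    if background is not None:
        if background.n != n:
            raise ValueError("background genotypes must cover the same individuals")
        pb = background.variants["freq"].to_numpy()
        raw = rng.standard_normal(background.m)
        hv = 2 * pb * (1 - pb)
        raw *= np.sqrt(h2_bg / np.sum(hv * raw**2)) if h2_bg > 0 else 0.0
        g_bg = (background.dosages @ raw.astype(background.dosages.dtype)).astype(np.float64)
        g_bg = g_bg - g_bg.mean()
    else:
        g_bg = rng.normal(0.0, np.sqrt(h2_bg), size=n) if h2_bg > 0 else np.zeros(n)

    var_resid = {}
    e = np.empty(n)
    for label, mask in (("M", males), ("F", ~males)):
        v = 1.0 - h2_bg - var_gx[label]
        if v <= 0:
            raise ValueError(
                f"implied residual variance {v:.4f} <= 0 in stratum {label}; "
                "lower h2x_f/h2_bg"
            )
        var_resid[label] = v
        e[mask] = rng.normal(0.0, np.sqrt(v), size=int(mask.sum()))

    y = g_x + g_bg + e
    y_std = np.empty(n)
    for mask in (males, ~males):
        y_std[mask] = (y[mask] - y[mask].mean()) / y[mask].std()
    return Phenotypes(y=y, y_std=y_std, sex=G.sex, var_gx=var_gx,
                      var_bg=h2_bg, var_resid=var_resid)


def simulate_expression(
    G: GenotypeMatrix,
    eqtl_spec: dict,
    seed=0,
) -> np.ndarray:
    """Single-eQTL expression trait with an optional mean sex difference.

    ``eqtl_spec`` keys: ``locus`` (variant index or id), ``variance_explained``
    (female-sample fraction, in [0, 0.65]), ``d`` (in [1, 2]) and
    ``mean_sex_diff`` (female minus male mean shift, trait SD units).
    Residual variance is ``1 - variance_explained`` in both sexes, so under
    dosage compensation the male expression variance (and male R^2) exceeds
    the female values — the genetic signal is genuinely stronger in
    hemizygous males.
    """
    locus = eqtl_spec["locus"]
    if not isinstance(locus, (int, np.integer)):
        hits = np.flatnonzero(G.variants["id"].to_numpy() == locus)
        if len(hits) == 0:
            raise ValueError(f"locus {locus!r} not in panel")
        locus = int(hits[0])
    ve = float(eqtl_spec.get("variance_explained", 0.0))
    d = float(eqtl_spec.get("d", 2.0))
    shift = float(eqtl_spec.get("mean_sex_diff", 0.0))
    if not 0 <= ve <= 0.65:
        raise ValueError("variance_explained must lie in [0, 0.65]")
    if not 1 <= d <= 2:
        raise ValueError("d must lie in [1, 2]")
    if G.variants["chrom_class"].iloc[locus] != X_NONPAR:
        raise ValueError("eQTL locus must be X non-PAR for X-mode traits")
    if G.coding != MALE_01:
        G = G.recode(MALE_01)
    rng = _rng(seed)
    p = float(G.variants["freq"].iloc[locus])
    beta_f = np.sqrt(ve / (2 * p * (1 - p))) if ve > 0 else 0.0
    beta_m = d * beta_f
    x = G.dosages[:, locus]
    males = G.is_male
    expr = np.where(males, x * beta_m, x * beta_f)
    expr = expr + shift * (~males)
    expr = expr + rng.normal(0.0, np.sqrt(1.0 - ve), size=G.n)
    return expr


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Declarative description of one simulation experiment."""

    n_m: int = 20_000
    n_f: int = 20_000
    m_x: int = 2_000
    m_auto: int = 0
    maf_range: tuple = (0.01, 0.5)
    m_causal: int = 200
    pi_escape: float = 0.0
    d_values: Optional[list] = None
    equal_var_per_locus: bool = True
    h2x_f: float = 0.01
    h2_bg: float = 0.0
    het_regions: list = field(default_factory=list)
    ld_blocks: list = field(default_factory=list)
    spacing_bp: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pi_escape <= 1:
            raise ValueError("pi_escape must lie in [0, 1]")
        if self.h2x_f < 0 or self.h2_bg < 0:
            raise ValueError("heritabilities must be >= 0")
        if self.h2x_f + self.h2_bg >= 1:
            raise ValueError("h2x_f + h2_bg must be < 1")
        if self.m_causal > self.m_x:
            raise ValueError("m_causal must not exceed m_x")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SimData:
    """One realised dataset: genotypes, truth, phenotypes."""

    config: SimConfig
    genotypes: GenotypeMatrix
    background: Optional[GenotypeMatrix]
    effects: EffectSet
    phenotypes: Phenotypes


def simulate_dataset(config: SimConfig, seed: Optional[int] = None) -> SimData:
    """Run the full generator for one config (seed overrides config.seed)."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed), 982451653])
    s_freq, s_geno, s_dc, s_eff, s_phen, s_auto = ss.spawn(6)
    freqs = draw_allele_frequencies(config.m_x, config.maf_range, s_freq)
    G = simulate_genotypes(
        freqs, config.n_m, config.n_f, X_NONPAR, s_geno,
        ld_blocks=config.ld_blocks or None, spacing_bp=config.spacing_bp,
    )
    d_causal = assign_dc_model(config.m_causal, config.pi_escape,
                               config.d_values, s_dc)
    E = draw_effects(
        freqs, d_causal, config.m_causal, config.h2x_f,
        config.equal_var_per_locus, config.het_regions or None, s_eff,
        positions=G.variants["bp"].to_numpy(),
    )
    background = None
    if config.m_auto > 0:
        bfreqs = draw_allele_frequencies(config.m_auto, config.maf_range, s_auto)
        background = simulate_genotypes(
            bfreqs, config.n_m, config.n_f, AUTOSOME, s_auto,
            spacing_bp=config.spacing_bp, prefix="auto",
        )
    phen = simulate_phenotypes(G, E, config.h2_bg, s_phen, background=background)
    return SimData(config=config, genotypes=G, background=background,
                   effects=E, phenotypes=phen)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write genotypes as VCF 4.2; male X non-PAR calls are emitted haploid."""
    G = G.recode(MALE_01)
    xmask = (G.variants["chrom_class"] == X_NONPAR).to_numpy()
    males = G.is_male
    names = [f"{'m' if s == 'M' else 'f'}{i}" for i, s in enumerate(G.sex)]
    gt_dip = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=X>\n##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j, row in enumerate(G.variants.itertuples(index=False)):
            calls = []
            for i in range(G.n):
                dose = int(G.dosages[i, j])
                if xmask[j] and males[i]:
                    calls.append(str(dose))
                else:
                    calls.append(gt_dip[dose])
            fh.write(
                f"{_CHROM_LABEL[row.chrom_class]}\t{row.bp}\t{row.id}\t{row.a2}\t"
                f"{row.a1}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path, sex: np.ndarray, chrom_class: str = X_NONPAR) -> GenotypeMatrix:
    """Read a VCF (haploid male X calls supported) into a GenotypeMatrix.

    ``sex`` gives per-sample labels in VCF sample order.  Allele-1 is ALT.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sex = np.asarray(sex)
    rows, meta = [], []
    for var in vcf:
        # gt_types with gts012: 0=hom-ref, 1=het, 2=hom-alt; haploid ALT
        # calls come back as hom-alt
        gts = np.array([sum(a for a in g[:-1] if a >= 0) for g in var.genotypes],
                       dtype=float)
        rows.append(gts)
        meta.append((var.ID, var.POS, var.ALT[0], var.REF))
    dosages = np.array(rows).T
    freqs = []
    for j, (vid, pos, a1, a2) in enumerate(meta):
        ploidy = np.where((chrom_class == X_NONPAR) & (sex == "M"), 1, 2)
        freqs.append(dosages[:, j].sum() / ploidy.sum())
    variants = pd.DataFrame(
        {
            "id": [mt[0] for mt in meta],
            "chrom_class": chrom_class,
            "bp": [mt[1] for mt in meta],
            "a1": [mt[2] for mt in meta],
            "a2": [mt[3] for mt in meta],
            "freq": freqs,
        }
    )
    return GenotypeMatrix(variants, sex, dosages, MALE_01)


def write_triplet(G: GenotypeMatrix, outdir) -> None:
    """Internal tab-delimited triplet: samples.tsv / variants.tsv / dosages.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample": np.arange(G.n), "sex": G.sex}).to_csv(
        outdir / "samples.tsv", sep="\t", index=False)
    G.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    np.savetxt(outdir / "dosages.tsv", G.dosages, fmt="%g", delimiter="\t")


def read_triplet(indir, coding: str = MALE_01) -> GenotypeMatrix:
    indir = Path(indir)
    samples = pd.read_csv(indir / "samples.tsv", sep="\t")
    variants = pd.read_csv(indir / "variants.tsv", sep="\t")
    dosages = np.loadtxt(indir / "dosages.tsv", delimiter="\t", ndmin=2)
    return GenotypeMatrix(variants, samples["sex"].to_numpy(), dosages, coding)


def write_truth(E: EffectSet, variants: pd.DataFrame, path) -> None:
    """Per-locus true parameters (beta_f, beta_m, d, delta) as TSV."""
    E.to_frame(variants).to_csv(path, sep="\t", index=False)
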