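"""Variance partitioning with genomic relationship matrices (GREML).

Fits ``y = g_G + g_X + e`` with ``g_G ~ N(0, A_G s2_G)`` from autosomal SNPs
and ``g_X ~ N(0, A_X s2_X)`` from X-chromosome SNPs by restricted maximum
likelihood, using average-information updates with EM fallback steps and
non-negativity by projection.  Sex-stratified fits use within-sex
column-standardised dosages, which sidesteps the cross-sex X-scaling
question entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import MALE_01, GenotypeMatrix


@dataclass
class GRM:
    """Genomic relationship matrix A = Z Z' / m with standardised dosages."""

    values: np.ndarray
    chrom_class: str
    n_snps: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class VarianceComponents:
    """REML estimates of (sigma2_G, sigma2_X, sigma2_e) and derived h2_X."""

    sigma2: np.ndarray           # per-component, residual last
    se: np.ndarray
    names: list
    loglik: float
    converged: bool
    iterations: int
    cov: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __getitem__(self, name: str) -> float:
        return float(self.sigma2[self.names.index(name)])

    @property
    def total(self) -> float:
        return float(self.sigma2.sum())

    def h2(self, name: str) -> float:
        return self[name] / self.total

    def h2_se(self, name: str) -> float:
        """Delta-method SE of a variance proportion from the AI covariance."""
        if self.cov.size == 0:
            return np.nan
        i = self.names.index(name)
        S = self.total
        grad = np.full(len(self.sigma2), -self.sigma2[i] / S**2)
        grad[i] += 1.0 / S
        return float(np.sqrt(grad @ self.cov @ grad))


def compute_grm(G: GenotypeMatrix, chrom_class: Optional[str] = None) -> GRM:
    """GRM from column-standardised dosages of one chromosome class.

    Standardisation uses the empirical mean/SD of the supplied individuals
    (so for sex-stratified use, pass a single-sex subset).  Missing dosages
    are mean-imputed; monomorphic SNPs are dropped.
    """
    if G.n < 2:
        raise ValueError("need at least 2 individuals")
    if chrom_class is not None:
        keep = (G.variants["chrom_class"] == chrom_class).to_numpy()
        if not keep.any():
            raise ValueError(f"no variants of class {chrom_class}")
        G = G.subset(variants=np.flatnonzero(keep))
    else:
        chrom_class = str(G.variants["chrom_class"].iloc[0])
    Z = np.array(G.dosages, dtype=float)
    col_mean = np.nanmean(Z, axis=0)
    nan_mask = np.isnan(Z)
    if nan_mask.any():
        Z[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = Z.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("all SNPs monomorphic in the supplied individuals")
    Z = (Z[:, poly] - col_mean[poly]) / sd[poly]
    m = int(poly.sum())
    return GRM(values=(Z @ Z.T) / m, chrom_class=chrom_class, n_snps=m)


def write_grm(grm: GRM, prefix) -> None:
    """Lower-triangle TSV (i, j, value) with an id sidecar; no binary dialect."""
    prefix = Path(prefix)
    n = grm.n
    tri = np.tril_indices(n)
    pd.DataFrame({"i": tri[0], "j": tri[1], "value": grm.values[tri]}).to_csv(
        f"{prefix}.grm.tsv", sep="\t", index=False)
    pd.DataFrame({"id": np.arange(n), "chrom_class": grm.chrom_class,
                  "n_snps": grm.n_snps}).to_csv(
        f"{prefix}.grm.ids.tsv", sep="\t", index=False)


def read_grm(prefix) -> GRM:
    prefix = Path(prefix)
    tri = pd.read_csv(f"{prefix}.grm.tsv", sep="\t")
    ids = pd.read_csv(f"{prefix}.grm.ids.tsv", sep="\t")
    n = len(ids)
    A = np.zeros((n, n))
    A[tri["i"], tri["j"]] = tri["value"]
    A = A + A.T - np.diag(np.diag(A))
    return GRM(A, str(ids["chrom_class"].iloc[0]), int(ids["n_snps"].iloc[0]))


def _reml_quantities(y, X, mats, theta):
    n = len(y)
    V = sum(t * A for t, A in zip(theta, mats))
    L = np.linalg.cholesky(V)
    Vinv = np.linalg.inv(V)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ y
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    ll = -0.5 * (logdetV + logdetX + y @ Py)
    return P, Py, ll


def reml_fit(
    y: np.ndarray,
    grms: Sequence[GRM],
    names: Optional[Sequence[str]] = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    X: Optional[np.ndarray] = None,
) -> VarianceComponents:
    """AI-REML for ``y = sum_i g_i + e`` with one random effect per GRM.

    The first iteration is an EM step (robust far from the optimum); later
    iterations use average-information updates with step-halving back toward
    the EM step whenever the restricted log-likelihood would decrease.
    Components are projected onto ``>= 1e-6 * var(y)``.  Convergence:
    relative log-likelihood change below ``tol``.  Standard errors come from
    the inverse average-information matrix.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    for g in grms:
        if g.n != n:
            raise ValueError("GRM dimension does not match phenotype length")
    mats = [g.values for g in grms] + [np.eye(n)]
    k = len(mats)
    if names is None:
        names = [f"sigma2_{g.chrom_class}" for g in grms] + ["sigma2_e"]
    names = list(names)
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    vp = float(np.var(y, ddof=1))
    floor = 1e-6 * vp
    theta = np.full(k, vp / k)

    P, Py, ll = _reml_quantities(y, X, mats, theta)
    converged = False
    it = 0
    AI = np.eye(k)
    for it in range(1, max_iter + 1):
        u = [A @ Py for A in mats]          # A_i P y
        w = [P @ ui for ui in u]            # P A_i P y
        yPAPy = np.array([Py @ ui for ui in u])
        trPA = np.array([np.sum(P * A) for A in mats])
        score = -0.5 * (trPA - yPAPy)
        AI = 0.5 * np.array([[u[i] @ w[j] for j in range(k)] for i in range(k)])
        em_step = theta**2 * (yPAPy - trPA) / n

        # min-norm solve tolerates a singular AI (e.g. an unidentifiable
        # component whose GRM contributes nothing)
        ai_step, *_ = np.linalg.lstsq(AI, score, rcond=None)
        if not np.all(np.isfinite(ai_step)):
            ai_step = em_step
        step = em_step if it == 1 else ai_step

        accepted = False
        for _ in range(20):  # step-halving toward the current point
            cand = np.maximum(theta + step, floor)
            try:
                P_new, Py_new, ll_new = _reml_quantities(y, X, mats, cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if ll_new >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:  # EM step as a last resort (never decreases ll)
            cand = np.maximum(theta + em_step, floor)
            P_new, Py_new, ll_new = _reml_quantities(y, X, mats, cand)
        delta = abs(ll_new - ll) / max(1.0, abs(ll))
        theta, P, Py = cand, P_new, Py_new
        ll_prev, ll = ll, ll_new
        if delta < tol:
            converged = True
            break

    cov = np.linalg.pinv(AI)  # = inverse information when AI is full rank
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return VarianceComponents(sigma2=theta, se=se, names=names, loglik=float(ll),
                              converged=converged, iterations=it, cov=cov)
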