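"""Genomic relationships, inbreeding, and variance components.

The repeatability animal model for a per-meiosis phenotype y (CC or rbar) of
FID i at meiosis j is

    y_ij = mu + b2 * F_i + a_i + pe_i + e_ij

with a ~ N(0, G Va) (G the VanRaden method-1 genomic relationship matrix),
pe ~ N(0, I Vpe) the permanent-environment effect and e ~ N(0, I Ve).
Heritability is h2 = Va / (Va + Vpe + Ve) and repeatability
t = (Va + Vpe) / (Va + Vpe + Ve).  Fits are per sex (sex-specific variance
components), with the individual moment inbreeding coefficient F as a fixed
covariate.  Because all covariates are FID-level the REML likelihood
factorizes exactly into FID means plus the pooled within-FID sum of squares,
which is the representation the AI-REML engine consumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .reml import RemlResult, reml_fit

log = logging.getLogger("meiokit")

__all__ = [
    "GRM",
    "vanraden_grm",
    "moment_inbreeding",
    "VarianceComponents",
    "fit_repeatability",
    "BivariateResult",
    "fit_bivariate",
]

RIDGE = 1e-6


@dataclass
class GRM:
    ids: list[str]
    matrix: np.ndarray
    freqs: np.ndarray
    method: str = "vanraden1"

    def __post_init__(self):
        self._index = {ind: i for i, ind in enumerate(self.ids)}

    def submatrix(self, ids1, ids2=None) -> np.ndarray:
        r = [self._index[i] for i in ids1]
        c = r if ids2 is None else [self._index[i] for i in ids2]
        return self.matrix[np.ix_(r, c)]


def _imputed_dosages(genotypes: GenotypeMatrix | np.ndarray):
    dos = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    dos = dos.astype(float)
    obs = dos >= 0
    dos[~obs] = np.nan
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(dos, axis=0) / 2.0
    return dos, freqs, obs


def vanraden_grm(genotypes: GenotypeMatrix | np.ndarray, ids=None, marker_mask=None) -> GRM:
    """VanRaden method-1 GRM: G = Z Z' / sum 2 p_j (1 - p_j), Z centered
    dosages with missing values mean-imputed, frequencies from the sample.
    Monomorphic markers are dropped."""
    if isinstance(genotypes, GenotypeMatrix):
        ids = list(genotypes.ids)
    elif ids is None:
        raise ValueError("ids required for a bare dosage array")
    if len(ids) < 2:
        raise ValueError("GRM needs at least two individuals")
    dos, freqs, _ = _imputed_dosages(genotypes)
    keep = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    if marker_mask is not None:
        keep &= marker_mask
    if not keep.any():
        raise ValueError("all markers monomorphic or masked")
    Z = dos[:, keep] - 2.0 * freqs[keep]
    Z = np.where(np.isnan(Z), 0.0, Z)  # mean-imputed -> centered to 0
    denom = float(np.sum(2.0 * freqs[keep] * (1.0 - freqs[keep])))
    G = Z @ Z.T / denom
    return GRM(list(ids), G, freqs[keep])


def moment_inbreeding(genotypes: GenotypeMatrix) -> pd.Series:
    """Method-of-moments inbreeding coefficient per individual:
    F = (O_hom - E_hom) / (m_obs - E_hom), with E_hom summed over that
    individual's non-missing polymorphic markers."""
    dos, freqs, obs = _imputed_dosages(genotypes)
    poly = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    usable = obs & poly
    two_pq = 2.0 * freqs * (1.0 - freqs)
    hom = (dos == 0) | (dos == 2)
    o_hom = np.where(usable, hom, False).sum(axis=1).astype(float)
    e_hom = (usable * (1.0 - two_pq)).sum(axis=1)
    m_obs = usable.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / (m_obs - e_hom)
    f[m_obs == 0] = np.nan
    return pd.Series(f, index=list(genotypes.ids), name="F")


def _collapse(obs: pd.DataFrame, value_col: str):
    """FID means, counts and pooled within-FID sum of squares."""
    g = obs.groupby("fid")[value_col]
    ybar = g.mean()
    n = g.count()
    ssw = float(((obs[value_col] - obs["fid"].map(ybar)) ** 2).sum())
    return ybar, n, ssw


@dataclass
class VarianceComponents:
    v_a: float
    v_pe: float
    v_e: float
    se_a: float
    se_pe: float
    se_e: float
    h2: float
    h2_se: float
    repeatability: float
    repeatability_se: float
    beta: np.ndarray
    beta_se: np.ndarray
    converged: bool
    n_iter: int
    loglik: float

    @property
    def v_p(self) -> float:
        return self.v_a + self.v_pe + self.v_e


def _ratio_se(num_idx, theta, ai_inv):
    """Delta-method SE of sum(theta[num_idx]) / sum(theta)."""
    tot = theta.sum()
    num = theta[num_idx].sum()
    grad = np.full(len(theta), -num / tot**2)
    grad[num_idx] += 1.0 / tot
    var = float(grad @ ai_inv @ grad)
    return np.sqrt(max(var, 0.0))


def fit_repeatability(
    observations: pd.DataFrame,
    grm: GRM,
    inbreeding: pd.Series | None = None,
    value_col: str = "value",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """AI-REML fit of the repeatability model for one sex.

    ``observations`` has one row per meiosis with columns ``fid`` and
    ``value_col``.  Observations whose FID lacks a GRM entry or (when an
    inbreeding covariate is supplied) an F value are dropped with a log entry.
    """
    obs = observations.rename(columns={value_col: "value"})[["fid", "value"]].copy()
    in_grm = obs["fid"].isin(grm._index)
    if not in_grm.all():
        log.info("dropping %d observations with FIDs absent from GRM", (~in_grm).sum())
        obs = obs[in_grm]
    if inbreeding is not None:
        has_f = obs["fid"].map(inbreeding).notna()
        if not has_f.all():
            log.info("dropping %d observations with missing F", (~has_f).sum())
            obs = obs[has_f]
    ybar, n, ssw = _collapse(obs, "value")
    fids = list(ybar.index)
    if len(fids) < 2:
        raise ValueError("need >= 2 FIDs")
    q = len(fids)
    N = int(n.sum())
    G = grm.submatrix(fids) + RIDGE * np.eye(q)
    D_inv = np.diag(1.0 / n.to_numpy(float))
    y = ybar.to_numpy(float)
    X = np.ones((q, 1))
    if inbreeding is not None:
        X = np.column_stack([X, inbreeding.reindex(fids).to_numpy(float)])
    vy = max(np.var(obs["value"], ddof=1), 1e-12)
    theta0 = np.array([0.3, 0.2, 0.5]) * vy
    res = reml_fit(
        y,
        X,
        [G, np.eye(q), D_inv],
        theta0,
        withins=[(2, ssw, float(N - q))],
        tol=tol,
        max_iter=max_iter,
    )
    v_a, v_pe, v_e = res.theta
    h2 = v_a / res.theta.sum()
    rep = (v_a + v_pe) / res.theta.sum()
    return VarianceComponents(
        v_a=v_a,
        v_pe=v_pe,
        v_e=v_e,
        se_a=res.se[0],
        se_pe=res.se[1],
        se_e=res.se[2],
        h2=h2,
        h2_se=_ratio_se([0], res.theta, res.ai_inv),
        repeatability=rep,
        repeatability_se=_ratio_se([0, 1], res.theta, res.ai_inv),
        beta=res.beta,
        beta_se=res.beta_se,
        converged=res.converged,
        n_iter=res.n_iter,
        loglik=res.loglik,
    )


@dataclass
class BivariateResult:
    v_a1: float
    v_a2: float
    cov_a: float
    r_g: float
    r_g_se: float
    v_pe1: float
    v_pe2: float
    v_e1: float
    v_e2: float
    converged: bool
    n_iter: int
    loglik: float
    r_g_defined: bool = True


def fit_bivariate(
    obs1: pd.DataFrame,
    obs2: pd.DataFrame,
    grm: GRM,
    value_col: str = "value",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> BivariateResult:
    """Bivariate AI-REML for the genetic correlation of two traits whose FID
    sets may be disjoint (cross-sex) or identical (two traits, one sex).

    The genetic (co)variance is a 2x2 matrix through the GRM; permanent
    environment and residual are trait-specific, and the residual covariance
    is structurally zero (no meiosis carries both traits).
    """
    y1, n1, ssw1 = _collapse(obs1.rename(columns={value_col: "value"}), "value")
    y2, n2, ssw2 = _collapse(obs2.rename(columns={value_col: "value"}), "value")
    f1, f2 = list(y1.index), list(y2.index)
    q1, q2 = len(f1), len(f2)
    q = q1 + q2
    G11 = grm.submatrix(f1) + RIDGE * np.eye(q1)
    G22 = grm.submatrix(f2) + RIDGE * np.eye(q2)
    G12 = grm.submatrix(f1, f2)

    def block(a, b, c):
        out = np.zeros((q, q))
        out[:q1, :q1] = a
        out[q1:, q1:] = c
        out[:q1, q1:] = b
        out[q1:, :q1] = b.T
        return out

    Z = np.zeros
    V_a1 = block(G11, Z((q1, q2)), Z((q2, q2)))
    V_a2 = block(Z((q1, q1)), Z((q1, q2)), G22)
    V_c = block(Z((q1, q1)), G12, Z((q2, q2)))
    V_pe1 = block(np.eye(q1), Z((q1, q2)), Z((q2, q2)))
    V_pe2 = block(Z((q1, q1)), Z((q1, q2)), np.eye(q2))
    V_e1 = block(np.diag(1.0 / n1.to_numpy(float)), Z((q1, q2)), Z((q2, q2)))
    V_e2 = block(Z((q1, q1)), Z((q1, q2)), np.diag(1.0 / n2.to_numpy(float)))

    y = np.concatenate([y1.to_numpy(float), y2.to_numpy(float)])
    X = np.zeros((q, 2))
    X[:q1, 0] = 1.0
    X[q1:, 1] = 1.0

    v1 = max(np.var(obs1[value_col], ddof=1), 1e-12)
    v2 = max(np.var(obs2[value_col], ddof=1), 1e-12)
    theta0 = np.array([0.3 * v1, 0.0, 0.3 * v2, 0.2 * v1, 0.2 * v2, 0.5 * v1, 0.5 * v2])
    is_var = np.array([True, False, True, True, True, True, True])
    res = reml_fit(
        y,
        X,
        [V_a1, V_c, V_a2, V_pe1, V_pe2, V_e1, V_e2],
        theta0,
        is_variance=is_var,
        withins=[(5, ssw1, float(n1.sum() - q1)), (6, ssw2, float(n2.sum() - q2))],
        tol=tol,
        max_iter=max_iter,
    )
    v_a1, cov_a, v_a2 = res.theta[0], res.theta[1], res.theta[2]
    scale = max(v1, v2)
    defined = v_a1 > 1e-8 * scale and v_a2 > 1e-8 * scale
    if defined:
        r_g = float(np.clip(cov_a / np.sqrt(v_a1 * v_a2), -1.0, 1.0))
        g = np.zeros(7)
        g[0] = -0.5 * cov_a / (v_a1**1.5 * np.sqrt(v_a2))
        g[1] = 1.0 / np.sqrt(v_a1 * v_a2)
        g[2] = -0.5 * cov_a / (v_a2**1.5 * np.sqrt(v_a1))
        r_g_se = float(np.sqrt(max(g @ res.ai_inv @ g, 0.0)))
    else:
        r_g, r_g_se = np.nan, np.nan
    return BivariateResult(
        v_a1=v_a1,
        v_a2=v_a2,
        cov_a=cov_a,
        r_g=r_g,
        r_g_se=r_g_se,
        v_pe1=res.theta[3],
        v_pe2=res.theta[4],
        v_e1=res.theta[5],
        v_e2=res.theta[6],
        converged=res.converged,
        n_iter=res.n_iter,
        loglik=res.loglik,
        r_g_defined=defined,
    )
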