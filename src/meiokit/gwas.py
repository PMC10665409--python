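"""Weighted leave-one-chromosome-out mixed-model association.

Per-meiosis phenotypes are collapsed to FID means; because the residual
variance of a mean of n repeated records shrinks with n, each mean gets a
residual-variance scale derived from the repeatability decomposition
Var(ybar_i) = Va + Vpe + Ve / n_i.  Relative to a single record,

    d_i = ((t - h2) + (1 - t) / n_i) / (1 - h2)

with h2 the heritability and t the repeatability of the trait, so d = 1 for
n = 1 and d -> (t - h2) / (1 - h2) as n grows.  The association model per
SNP is ybar = a + b x + g + e with g ~ N(0, G_loco sigma_a^2) excluding the
focal SNP's chromosome from the relationship matrix and e ~ N(0, D sigma_e^2),
D = diag(d_i).  Null variance components are re-estimated by REML for every
left-out chromosome; each SNP is then tested by generalized least squares
with a 1-df Wald chi-square.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .containers import GenomeSpec, GenotypeMatrix, MarkerPanel
from .quantgen import GRM, vanraden_grm
from .reml import reml_fit

log = logging.getLogger("meiokit")

__all__ = ["collapse_and_weight", "bonferroni_threshold", "mlma_loco", "GwasResult"]


def collapse_and_weight(
    observations: pd.DataFrame,
    h2: float,
    t: float,
    value_col: str = "value",
) -> pd.DataFrame:
    """FID means with observation counts and residual-variance scales d_i."""
    if not (0 <= h2 <= t < 1):
        raise ValueError("need 0 <= h2 <= t < 1")
    g = observations.groupby("fid")[value_col]
    out = pd.DataFrame({"ybar": g.mean(), "n": g.count()})
    out["d"] = ((t - h2) + (1.0 - t) / out["n"]) / (1.0 - h2)
    return out.reset_index()


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class GwasResult:
    table: pd.DataFrame  # chrom, pos_bp, marker, beta, se, p, significant
    threshold: float
    varcomp: dict[str, tuple[float, float]]  # per left-out chromosome


def mlma_loco(
    means: pd.DataFrame,
    genotypes: GenotypeMatrix,
    genome: GenomeSpec,
    alpha: float = 0.05,
    weighted: bool = True,
) -> GwasResult:
    """Mixed-linear-model association with a leave-one-chromosome-out GRM.

    ``means`` has columns fid, ybar, n, d (from :func:`collapse_and_weight`);
    set ``weighted=False`` for D = I.
    """
    panel = genotypes.panel
    chroms = [c for c in genome.chrom_ids if c in panel.chromosomes]
    if len(chroms) < 2:
        raise ValueError("LOCO needs at least two chromosomes")
    fids = list(means["fid"])
    geno = genotypes.subset(fids)
    y = means["ybar"].to_numpy(float)
    d = means["d"].to_numpy(float) if weighted else np.ones(len(fids))
    D = np.diag(d)
    X0 = np.ones((len(fids), 1))
    chrom_of = np.asarray(panel.chrom_ids)

    imput = geno.dosages.astype(float)
    imput[imput < 0] = np.nan
    col_mean = np.nanmean(imput, axis=0)
    imput = np.where(np.isnan(imput), col_mean, imput)

    rows = []
    varcomp: dict[str, tuple[float, float]] = {}
    vy = max(np.var(y, ddof=1), 1e-12)
    for c in chroms:
        loco_mask = chrom_of != c
        G = vanraden_grm(geno.dosages, ids=fids, marker_mask=loco_mask).matrix
        G += 1e-6 * np.eye(len(fids))
        res = reml_fit(
            y, X0, [G, D], np.array([0.5, 0.5]) * vy, tol=1e-8, max_iter=100
        )
        s2a, s2e = res.theta
        varcomp[c] = (s2a, s2e)
        V = s2a * G + s2e * D
        cf = cho_factor(V, lower=True)
        snp_idx = np.flatnonzero(chrom_of == c)
        Vi_y = cho_solve(cf, y)
        Vi_1 = cho_solve(cf, X0[:, 0])
        for j in snp_idx:
            x = imput[:, j]
            if np.var(x) < 1e-12:
                continue
            Vi_x = cho_solve(cf, x)
            # GLS for [1, x]
            A = np.array(
                [
                    [float(X0[:, 0] @ Vi_1), float(X0[:, 0] @ Vi_x)],
                    [float(x @ Vi_1), float(x @ Vi_x)],
                ]
            )
            rhs = np.array([float(X0[:, 0] @ Vi_y), float(x @ Vi_y)])
            try:
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                log.warning("singular equations at %s; SNP skipped", panel.marker_ids[j])
                continue
            bhat = Ainv @ rhs
            se = np.sqrt(max(Ainv[1, 1], 0.0))
            wald = (bhat[1] / se) ** 2 if se > 0 else 0.0
            p = float(chi2.sf(wald, 1))
            rows.append(
                {
                    "chrom": c,
                    "pos_bp": panel.pos_bp[j],
                    "marker": panel.marker_ids[j],
                    "beta": bhat[1],
                    "se": se,
                    "p": max(p, np.finfo(float).tiny),
                }
            )
    table = pd.DataFrame(rows)
    thr = bonferroni_threshold(len(table), alpha) if len(table) else np.nan
    if len(table):
        table["significant"] = table["p"] < thr
    return GwasResult(table=table, threshold=thr, varcomp=varcomp)
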