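"""Restricted maximum likelihood for linear covariance structures.

Fits y ~ N(X b, sum_r theta_r V_r) by average-information (AI) REML with an
EM-gradient warm-up.  Models with repeated records enter through optional
"within" terms: a parameter that also scales an i.i.d. within-group part
contributes df * log(theta) + ssw / theta to -2 logL, which is the exact
collapsed representation of a repeatability model whose covariates are all
group-level (group means + pooled within-group sum of squares).

AI steps that would decrease the restricted log-likelihood are step-halved
and ultimately replaced by an EM-gradient step, so logL is non-decreasing
across iterations; variance-type parameters are floored, covariance-type
parameters are unconstrained.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["RemlResult", "reml_fit"]


@dataclass
class RemlResult:
    theta: np.ndarray
    se: np.ndarray
    beta: np.ndarray
    beta_se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    ai_inv: np.ndarray


def _neg2_loglik_parts(theta, y, X, V_list, withins):
    """Returns (-2 logL, aux) or (None, None) when Sigma is not PD."""
    q = len(y)
    sigma = np.zeros((q, q))
    for t, V in zip(theta, V_list):
        sigma += t * V
    try:
        c, low = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError:
        return None, None
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    si_y = cho_solve((c, low), y)
    si_X = cho_solve((c, low), X)
    XtSiX = X.T @ si_X
    try:
        cx = cho_factor(XtSiX, lower=True)
    except np.linalg.LinAlgError:
        return None, None
    logdet_xx = 2.0 * np.sum(np.log(np.diag(cx[0])))
    XtSiy = X.T @ si_y
    beta = cho_solve(cx, XtSiy)
    Py = si_y - si_X @ beta
    n2ll = logdet_sigma + logdet_xx + float(y @ Py)
    for idx, ssw, df in withins:
        n2ll += df * np.log(theta[idx]) + ssw / theta[idx]
    aux = {
        "chol": (c, low),
        "si_X": si_X,
        "XtSiX_chol": cx,
        "beta": beta,
        "Py": Py,
    }
    return n2ll, aux


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    V_list: list[np.ndarray],
    theta0: np.ndarray,
    is_variance: np.ndarray | None = None,
    withins: list[tuple[int, float, float]] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    em_iters: int = 3,
    floor_frac: float = 1e-10,
) -> RemlResult:
    """AI-REML with EM warm-up.

    ``withins`` is a list of (theta index, within-group SS, within df).
    ``is_variance`` marks parameters constrained to be >= floor (default all).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    theta = np.asarray(theta0, dtype=float).copy()
    n_par = len(theta)
    if is_variance is None:
        is_variance = np.ones(n_par, dtype=bool)
    withins = withins or []
    within_df = {idx: (ssw, df) for idx, ssw, df in withins}
    q = len(y)
    scale = max(float(np.var(y)), 1e-12)
    floor = floor_frac * scale
    theta[is_variance] = np.maximum(theta[is_variance], floor)

    n2ll, aux = _neg2_loglik_parts(theta, y, X, V_list, withins)
    if n2ll is None:
        raise np.linalg.LinAlgError("initial covariance not positive definite")

    converged = False
    it = 0
    ai = np.eye(n_par)
    for it in range(1, max_iter + 1):
        c = aux["chol"]
        si_X = aux["si_X"]
        cx = aux["XtSiX_chol"]
        Py = aux["Py"]

        def P_dot(M):  # P @ M without forming P
            siM = cho_solve(c, M)
            return siM - si_X @ cho_solve(cx, si_X.T @ M)

        PV = [P_dot(V) for V in V_list]
        VPy = [V @ Py for V in V_list]
        trace = np.array([np.trace(pv) for pv in PV])
        quad = np.array([float(Py @ v) for v in VPy])
        # within-part contributions (residual-type parameters)
        for idx, (ssw, df) in within_df.items():
            trace[idx] += df / theta[idx]
            quad[idx] += ssw / theta[idx] ** 2
        score = 0.5 * (quad - trace)

        PVPy = [P_dot(v) for v in VPy]
        ai = 0.5 * np.array(
            [[float(VPy[r] @ PVPy[s]) for s in range(n_par)] for r in range(n_par)]
        )
        for idx, (ssw, df) in within_df.items():
            ai[idx, idx] += df / (2.0 * theta[idx] ** 2)
        ai = 0.5 * (ai + ai.T)

        def em_step():
            new = theta.copy()
            for r in range(n_par):
                if not is_variance[r]:
                    continue
                w = q + (within_df[r][1] if r in within_df else 0.0)
                new[r] = theta[r] + theta[r] ** 2 * (quad[r] - trace[r]) / w
            return np.where(is_variance, np.maximum(new, floor), new)

        if it <= em_iters:
            cand = em_step()
        else:
            try:
                delta = np.linalg.solve(ai + 1e-12 * np.eye(n_par), score)
            except np.linalg.LinAlgError:
                delta = score / np.maximum(np.diag(ai), 1e-12)
            cand = theta + delta
            cand = np.where(is_variance, np.maximum(cand, floor), cand)

        new_n2ll, new_aux = _neg2_loglik_parts(cand, y, X, V_list, withins)
        halvings = 0
        while (new_n2ll is None or new_n2ll > n2ll + 1e-10) and halvings < 8:
            cand = theta + 0.5 ** (halvings + 1) * (cand - theta)
            cand = np.where(is_variance, np.maximum(cand, floor), cand)
            new_n2ll, new_aux = _neg2_loglik_parts(cand, y, X, V_list, withins)
            halvings += 1
        if new_n2ll is None or new_n2ll > n2ll + 1e-10:
            # gradient line search: EM alone cannot move covariance-type
            # parameters, so ascend along the score first
            g_norm = float(np.max(np.abs(score)))
            if g_norm > 0:
                t0 = 0.5 * float(np.max(np.abs(theta)) + floor) / g_norm
                for k in range(20):
                    cand = theta + score * t0 * 0.5**k
                    cand = np.where(is_variance, np.maximum(cand, floor), cand)
                    new_n2ll, new_aux = _neg2_loglik_parts(cand, y, X, V_list, withins)
                    if new_n2ll is not None and new_n2ll <= n2ll + 1e-10:
                        break
        if new_n2ll is None or new_n2ll > n2ll + 1e-10:
            cand = em_step()
            new_n2ll, new_aux = _neg2_loglik_parts(cand, y, X, V_list, withins)
            if new_n2ll is None:
                break
        change = n2ll - new_n2ll
        theta, n2ll, aux = cand, new_n2ll, new_aux
        if it > em_iters and abs(change) < tol:
            converged = True
            break

    try:
        ai_inv = np.linalg.inv(ai + 1e-12 * np.eye(n_par))
    except np.linalg.LinAlgError:
        ai_inv = np.full((n_par, n_par), np.nan)
    beta = aux["beta"]
    beta_cov = np.linalg.inv(aux["si_X"].T @ X)
    return RemlResult(
        theta=theta,
        se=np.sqrt(np.maximum(np.diag(ai_inv), 0.0)),
        beta=beta,
        beta_se=np.sqrt(np.maximum(np.diag(beta_cov), 0.0)),
        loglik=-0.5 * n2ll,
        converged=converged,
        n_iter=it,
        ai_inv=ai_inv,
    )
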