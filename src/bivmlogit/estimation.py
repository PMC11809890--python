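"""Maximum-likelihood estimation of the bivariate two-level model.

The marginal likelihood integrates the zonal random effect(s) out of the
conditional joint likelihood.  The integral is approximated per cluster by
the Laplace method: a damped Newton search finds the mode of the
conditional log-likelihood-plus-prior, and the integral is replaced by the
Gaussian one matching the mode and curvature there,

    log integral ~ l(u_hat) + (d/2) log 2pi - (1/2) log det(-H(u_hat)).

Adaptive Gauss-Hermite quadrature (nodes recentred and rescaled at the
Laplace mode) is provided as a cross-check; one node reproduces Laplace
exactly.  ``sigma = 0`` is handled exactly (the integral degenerates to
the fixed-effect likelihood).

The outer maximization is quasi-Newton (L-BFGS-B) over
``(beta1, beta2, alpha, log sigma [, atanh rho])`` with finite-difference
gradients; standard errors come from the inverse of a central-difference
Hessian of the marginal log-likelihood at the optimum.  Inference is Wald
throughout, significance at 0.05, no multiplicity correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .data_model import AnalysisTable, DesignMatrices, encode_design
from .model import (
    LOGISTIC_RESIDUAL_VARIANCE,
    ModelLevel,
    Parameters,
    log_re_density,
    unit_loglik_and_grads,
)

__all__ = [
    "ConvergenceError",
    "FitResult",
    "LadderResult",
    "icc",
    "information_criteria",
    "laplace_marginal_loglik",
    "agq_marginal_loglik",
    "fit",
    "model_ladder",
]

#: the rounded value of pi^2/3 conventionally printed in survey reports;
#: computations use LOGISTIC_RESIDUAL_VARIANCE, displays quote this.
ICC_DISPLAY_CONSTANT = 3.29

_MODE_TOL = 1e-10
_MODE_MAXITER = 100
_FD_H = 1e-5


class ConvergenceError(RuntimeError):
    """An inner mode search or the outer optimizer failed to converge."""


def icc(sigma2) -> float:
    """Latent-threshold intraclass correlation ``sigma2 / (sigma2 + pi^2/3)``.

    The level-1 residual of the latent logistic formulation has variance
    pi^2/3 (= 3.2898..., conventionally printed as 3.29), so the ICC is the
    share of latent variance attributable to the zones.
    """
    sigma2 = float(sigma2)
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    return sigma2 / (sigma2 + LOGISTIC_RESIDUAL_VARIANCE)


def information_criteria(loglik: float, p_count: int, n_units: int,
                         n_clusters: int, bic_n: str = "clusters"):
    """AIC and BIC for a fitted model.

    ``aic = -2 loglik + 2 p``; ``bic = -2 loglik + p ln(n)`` with ``n`` the
    number of level-2 units (clusters) by default — the convention of
    mixed-model software fitted by Laplace — or ``bic_n="units"`` for the
    unit count.
    """
    if p_count < 1:
        raise ValueError("p_count must be >= 1")
    n = n_clusters if bic_n == "clusters" else n_units
    aic = -2.0 * loglik + 2.0 * p_count
    bic = -2.0 * loglik + p_count * np.log(n)
    return float(aic), float(bic)


# ---------------------------------------------------------------------------
# marginal likelihood internals


def _arrays(table: AnalysisTable, design: DesignMatrices, weighted: bool):
    rows = design.row_index
    y1 = table.data["y1"].to_numpy()[rows].astype(float)
    y2 = table.data["y2"].to_numpy()[rows].astype(float)
    if weighted:
        w = table.data["weight"].to_numpy(float)[rows]
    else:
        w = np.ones(len(rows))
    return y1, y2, w


def _degenerate(params: Parameters) -> bool:
    return all(s == 0.0 for s in params.sigma[:params.re_dim])


def _fixed_effect_loglik(params, design, y1, y2, w) -> float:
    eta1 = design.X1 @ params.beta1
    eta2 = design.X2 @ params.beta2
    logp, _, _ = unit_loglik_and_grads(y1, y2, eta1, eta2, params.psi)
    return float((w * logp).sum())


def _mode_shared(params, design, y1, y2, w, u0):
    """Vectorized damped Newton for the shared (scalar-per-cluster) mode.

    Curvature is obtained by central differencing the analytic gradient of
    the data part (the prior part is linear in u, so its Hessian -1/s^2 is
    exact).  Returns (u_hat, H at mode, per-cluster objective at mode).
    """
    C = design.n_clusters
    idx = design.cluster_index
    s2 = params.sigma[0] ** 2
    Xb1 = design.X1 @ params.beta1
    Xb2 = design.X2 @ params.beta2
    psi = params.psi
    const = -0.5 * np.log(2.0 * np.pi * s2)

    def parts(u):
        eta1 = Xb1 + u[idx]
        eta2 = Xb2 + u[idx]
        logp, g1, g2 = unit_loglik_and_grads(y1, y2, eta1, eta2, psi)
        ll = np.bincount(idx, weights=w * logp, minlength=C)
        gd = np.bincount(idx, weights=w * (g1 + g2), minlength=C)
        return ll, gd

    def fval(u, ll_data):
        return ll_data - 0.5 * u * u / s2 + const

    u = u0.copy()
    ll_d, gd = parts(u)
    f = fval(u, ll_d)
    converged = False
    for _ in range(_MODE_MAXITER):
        g = gd - u / s2
        if np.max(np.abs(g)) < _MODE_TOL * (1.0 + 1.0 / s2):
            converged = True
            break
        h = _FD_H * (1.0 + np.abs(u))
        _, gp = parts(u + h)
        _, gm = parts(u - h)
        H = (gp - gm) / (2.0 * h) - 1.0 / s2
        H = np.minimum(H, -1e-10)
        step = np.clip(-g / H, -5.0, 5.0)
        for _ in range(40):
            ll_new, gd_new = parts(u + step)
            f_new = fval(u + step, ll_new)
            bad = f_new < f - 1e-13
            if not bad.any():
                break
            step = np.where(bad, 0.5 * step, step)
        else:
            ll_new, gd_new = parts(u + step)
            f_new = fval(u + step, ll_new)
        if np.max(np.abs(step)) < 1e-13:
            converged = True
            u, f, gd = u + step, f_new, gd_new
            break
        u, f, gd = u + step, f_new, gd_new
    else:
        g = gd - u / s2
        converged = np.max(np.abs(g)) < 1e-6 * (1.0 + 1.0 / s2)
    if not converged:
        g = gd - u / s2
        worst = design.cluster_ids[int(np.argmax(np.abs(g)))]
        raise ConvergenceError(
            f"random-effect mode search did not converge (cluster {worst!r})")
    h = _FD_H * (1.0 + np.abs(u))
    _, gp = parts(u + h)
    _, gm = parts(u - h)
    H = np.minimum((gp - gm) / (2.0 * h) - 1.0 / s2, -1e-10)
    return u, H, f


def _re_precision(params: Parameters) -> np.ndarray:
    s1, s2 = params.sigma[0], params.sigma[1]
    if params.re_structure == "independent":
        return np.diag([1.0 / s1 ** 2, 1.0 / s2 ** 2])
    rho = params.sigma[2]
    cov = np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])
    return np.linalg.inv(cov)


def _mode_bivariate(params, design, y1, y2, w, u0):
    """Damped Newton for two effects per cluster (independent/correlated)."""
    C = design.n_clusters
    idx = design.cluster_index
    Xb1 = design.X1 @ params.beta1
    Xb2 = design.X2 @ params.beta2
    psi = params.psi
    Sinv = _re_precision(params)

    def parts(u):
        eta1 = Xb1 + u[idx, 0]
        eta2 = Xb2 + u[idx, 1]
        logp, g1, g2 = unit_loglik_and_grads(y1, y2, eta1, eta2, psi)
        ll = np.bincount(idx, weights=w * logp, minlength=C)
        G = np.column_stack([
            np.bincount(idx, weights=w * g1, minlength=C),
            np.bincount(idx, weights=w * g2, minlength=C),
        ])
        return ll, G

    def fval(u, ll_data):
        return ll_data + log_re_density(params, u)

    def data_hessians(u):
        H = np.empty((C, 2, 2))
        for j in range(2):
            h = _FD_H * (1.0 + np.abs(u[:, j]))
            up = u.copy(); up[:, j] += h
            um = u.copy(); um[:, j] -= h
            _, Gp = parts(up)
            _, Gm = parts(um)
            H[:, :, j] = (Gp - Gm) / (2.0 * h)[:, None]
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))

    u = u0.copy()
    ll_d, Gd = parts(u)
    f = fval(u, ll_d)
    converged = False
    for _ in range(_MODE_MAXITER):
        g = Gd - u @ Sinv
        if np.max(np.abs(g)) < _MODE_TOL * (1.0 + np.max(Sinv)):
            converged = True
            break
        H = data_hessians(u) - Sinv[None, :, :]
        a, b, d = H[:, 0, 0], H[:, 0, 1], H[:, 1, 1]
        det = a * d - b * b
        ok = (det > 0) & (a < 0)
        step = np.empty_like(u)
        step[:, 0] = -(d * g[:, 0] - b * g[:, 1]) / np.where(ok, det, 1.0)
        step[:, 1] = -(-b * g[:, 0] + a * g[:, 1]) / np.where(ok, det, 1.0)
        step[~ok] = 0.1 * g[~ok]          # gradient-ascent fallback
        step = np.clip(step, -5.0, 5.0)
        for _ in range(40):
            ll_new, G_new = parts(u + step)
            f_new = fval(u + step, ll_new)
            bad = f_new < f - 1e-13
            if not bad.any():
                break
            step = np.where(bad[:, None], 0.5 * step, step)
        else:
            ll_new, G_new = parts(u + step)
            f_new = fval(u + step, ll_new)
        if np.max(np.abs(step)) < 1e-13:
            u, f, Gd = u + step, f_new, G_new
            converged = True
            break
        u, f, Gd = u + step, f_new, G_new
    else:
        g = Gd - u @ Sinv
        converged = np.max(np.abs(g)) < 1e-6 * (1.0 + np.max(Sinv))
    if not converged:
        g = Gd - u @ Sinv
        worst = design.cluster_ids[int(np.argmax(np.max(np.abs(g), axis=1)))]
        raise ConvergenceError(
            f"random-effect mode search did not converge (cluster {worst!r})")
    H = data_hessians(u) - Sinv[None, :, :]
    return u, H, f


def _laplace_parts(params, design, y1, y2, w, u0=None):
    C = design.n_clusters
    if params.re_structure == "shared":
        u0 = np.zeros(C) if u0 is None or u0.shape != (C,) else u0
        u, H, f = _mode_shared(params, design, y1, y2, w, u0)
        total = float(np.sum(f + 0.5 * np.log(2.0 * np.pi)
                             - 0.5 * np.log(-H)))
        return total, u, H
    u0 = np.zeros((C, 2)) if u0 is None or u0.shape != (C, 2) else u0
    u, H, f = _mode_bivariate(params, design, y1, y2, w, u0)
    det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2   # det(-H) = det(H), d=2
    det = np.maximum(det, 1e-300)
    total = float(np.sum(f + np.log(2.0 * np.pi) - 0.5 * np.log(det)))
    return total, u, H


def laplace_marginal_loglik(params: Parameters, design: DesignMatrices,
                            table: AnalysisTable, weighted: bool = False) -> float:
    """Laplace-approximated marginal log-likelihood (exact when sigma = 0)."""
    y1, y2, w = _arrays(table, design, weighted)
    if design.n_clusters < 2 and not _degenerate(params):
        pass  # a single cluster is still integrable; the *fit* requires >= 2
    if _degenerate(params):
        return _fixed_effect_loglik(params, design, y1, y2, w)
    if any(s == 0.0 for s in params.sigma[:params.re_dim]):
        raise ValueError("mixed zero/nonzero random-effect scales")
    total, _, _ = _laplace_parts(params, design, y1, y2, w)
    return total


def agq_marginal_loglik(params: Parameters, design: DesignMatrices,
                        table: AnalysisTable, nodes: int,
                        weighted: bool = False) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood.

    Nodes are recentred at the Laplace mode and rescaled by the curvature
    there; ``nodes=1`` reproduces the Laplace value identically.  Supports
    the shared (d=1) and independent/correlated (d=2, tensor grid)
    structures.
    """
    if nodes < 1:
        raise ValueError("nodes must be >= 1")
    y1, y2, w = _arrays(table, design, weighted)
    if _degenerate(params):
        return _fixed_effect_loglik(params, design, y1, y2, w)
    _, u_hat, H = _laplace_parts(params, design, y1, y2, w)
    C = design.n_clusters
    idx = design.cluster_index
    Xb1 = design.X1 @ params.beta1
    Xb2 = design.X2 @ params.beta2
    psi = params.psi
    z, wq = np.polynomial.hermite.hermgauss(nodes)

    def cluster_f(u):
        eta1 = Xb1 + u[idx] if u.ndim == 1 else Xb1 + u[idx, 0]
        eta2 = Xb2 + u[idx] if u.ndim == 1 else Xb2 + u[idx, 1]
        logp, _, _ = unit_loglik_and_grads(y1, y2, eta1, eta2, psi)
        return (np.bincount(idx, weights=w * logp, minlength=C)
                + log_re_density(params, u))

    if params.re_structure == "shared":
        lam = -H
        scale = np.sqrt(2.0 / lam)
        terms = np.empty((nodes, C))
        for k in range(nodes):
            terms[k] = cluster_f(u_hat + z[k] * scale) + z[k] ** 2 + np.log(wq[k])
        m = terms.max(axis=0)
        per_cluster = m + np.log(np.exp(terms - m).sum(axis=0)) \
            + 0.5 * np.log(2.0 / lam)
        return float(per_cluster.sum())

    # d = 2: per-cluster Cholesky factor A of (-H)^(-1), tensor-product grid
    lam = -H
    a, b, d = lam[:, 0, 0], lam[:, 0, 1], lam[:, 1, 1]
    det = np.maximum(a * d - b * b, 1e-300)
    # inv(lam) = [[d, -b], [-b, a]] / det; its Cholesky (lower) per cluster
    i11, i12, i22 = d / det, -b / det, a / det
    L11 = np.sqrt(np.maximum(i11, 1e-300))
    L21 = i12 / L11
    L22 = np.sqrt(np.maximum(i22 - L21 ** 2, 1e-300))
    terms = np.empty((nodes * nodes, C))
    r = 0
    for k in range(nodes):
        for m_ in range(nodes):
            zz = np.column_stack([
                L11 * z[k],
                L21 * z[k] + L22 * z[m_],
            ]) * np.sqrt(2.0)
            terms[r] = (cluster_f(u_hat + zz)
                        + z[k] ** 2 + z[m_] ** 2 + np.log(wq[k] * wq[m_]))
            r += 1
    m = terms.max(axis=0)
    per_cluster = m + np.log(np.exp(terms - m).sum(axis=0)) \
        + np.log(2.0) + 0.5 * np.log(L11 ** 2 * L22 ** 2)
    return float(per_cluster.sum())


# ---------------------------------------------------------------------------
# fitting


def _irls(X, y, w, iters=30, ridge=1e-8):
    """Plain weighted IRLS logistic fit (used only for initialization)."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = np.clip(X @ beta, -30, 30)
        p = expit(eta)
        W = w * p * (1.0 - p) + 1e-10
        A = (X * W[:, None]).T @ X + ridge * np.eye(X.shape[1])
        g = X.T @ (w * (y - p))
        step = np.linalg.solve(A, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _crude_log_or(y1, y2):
    n11 = float(((y1 == 1) & (y2 == 1)).sum()) + 0.5
    n10 = float(((y1 == 1) & (y2 == 0)).sum()) + 0.5
    n01 = float(((y1 == 0) & (y2 == 1)).sum()) + 0.5
    n00 = float(((y1 == 0) & (y2 == 0)).sum()) + 0.5
    return float(np.clip(np.log(n11 * n00 / (n10 * n01)), -4.0, 4.0))


def _sigma0(y1, y2, idx, C):
    """Empirical-logit moment guess for the zonal scale (0.5^0.5 if degenerate)."""
    vals = []
    n = np.bincount(idx, minlength=C).astype(float)
    for y in (y1, y2):
        k = np.bincount(idx, weights=y, minlength=C)
        el = np.log((k + 0.5) / (n - k + 0.5))
        vals.append(float(np.var(el)))
    s2 = np.nanmean(vals)
    if not np.isfinite(s2) or s2 <= 0:
        s2 = 0.5
    return float(np.sqrt(np.clip(s2, 0.04, 4.0)))


@dataclass
class FitResult:
    """A fitted bivariate two-level model."""

    params: Parameters
    free_names: tuple[str, ...]
    theta: np.ndarray
    se: np.ndarray                    # NaN where unavailable
    ses_available: bool
    loglik: float
    aic: float
    bic: float
    p_count: int
    icc: dict                         # outcome -> latent-scale ICC
    sigma2: tuple
    association_or: dict | None       # estimate / ci_low / ci_high / p
    aor_table: pd.DataFrame
    n_units: int
    n_clusters: int
    converged: bool
    n_iter: int
    grad_norm: float
    message: str
    level_label: str = "custom"
    weighted: bool = False

    def se_for(self, name: str) -> float:
        try:
            return float(self.se[self.free_names.index(name)])
        except ValueError:
            return float("nan")

    def estimate_for(self, name: str) -> float:
        return float(self.theta[self.free_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "level": self.level_label,
            "params": self.params.to_dict(),
            "free_names": list(self.free_names),
            "theta": self.theta.tolist(),
            "se": [None if not np.isfinite(s) else float(s) for s in self.se],
            "ses_available": self.ses_available,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "p_count": self.p_count,
            "icc": self.icc,
            "icc_display_constant": ICC_DISPLAY_CONSTANT,
            "sigma2": list(self.sigma2),
            "association_or": self.association_or,
            "n_units": self.n_units,
            "n_clusters": self.n_clusters,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "message": self.message,
            "weighted": self.weighted,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _aor_frame(names1, names2, beta1, beta2, se_map, level=0.95):
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    rows = []
    # near-separated terms legitimately yield inf CI bounds
    with np.errstate(over="ignore"):
        for outcome, names, beta in (("y1", names1, beta1), ("y2", names2, beta2)):
            for name, b in zip(names, beta):
                se = se_map.get(f"{outcome}:{name}", float("nan"))
                zval = b / se if se and np.isfinite(se) and se > 0 else float("nan")
                p = 2.0 * stats.norm.sf(abs(zval)) if np.isfinite(zval) else float("nan")
                rows.append({
                    "outcome": outcome,
                    "term": name,
                    "beta": float(b),
                    "se": float(se),
                    "aor": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se))
                    if np.isfinite(se) else float("nan"),
                    "ci_high": float(np.exp(b + z * se))
                    if np.isfinite(se) else float("nan"),
                    "p": float(p) if np.isfinite(p) else float("nan"),
                    "significant": bool(np.isfinite(p) and p < 0.05),
                })
    return pd.DataFrame(rows)


def _numeric_hessian(fun, x, rel_step=1e-4):
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            fa = fun(x + ei + ej)
            fb = fun(x + ei - ej)
            fc = fun(x - ei + ej)
            fd = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd) / (4.0 * h[i] * h[j])
    return H


def fit(level: ModelLevel, table: AnalysisTable, schema=None, *,
        re_structure: str = "shared", weighted: bool = False,
        fix_alpha: float | None = None, fix_sigma=None,
        se: bool = True, maxiter: int = 500) -> FitResult:
    """Fit the bivariate two-level model by Laplace maximum likelihood.

    Parameters
    ----------
    level : ModelLevel
        Covariate sets for the two marginal predictors.
    fix_alpha : float, optional
        Hold the log odds-ratio association fixed (0 = independence).
    fix_sigma : float or tuple, optional
        Hold the random-effect scale(s) fixed; ``0`` gives the
        fixed-effect (single-level) model.
    se : bool
        Compute Wald standard errors from a finite-difference Hessian
        (skip for speed in ladders and simulations that only need the
        point fit).
    """
    schema = schema if schema is not None else table.schema
    design = encode_design(table, level.covariates1, level.covariates2, schema)
    y1, y2, w = _arrays(table, design, weighted)

    sigma_fixed = fix_sigma is not None
    if sigma_fixed and np.isscalar(fix_sigma):
        fix_sigma_t = {"shared": (float(fix_sigma),),
                       "independent": (float(fix_sigma),) * 2,
                       "correlated": (float(fix_sigma), float(fix_sigma), 0.0),
                       }[re_structure]
    elif sigma_fixed:
        fix_sigma_t = tuple(float(s) for s in fix_sigma)
    else:
        fix_sigma_t = None

    multilevel = not (sigma_fixed and all(s == 0 for s in fix_sigma_t[:2]))
    if multilevel and design.n_clusters < 2:
        raise ValueError("at least 2 clusters are required for a multilevel fit")

    k1, k2 = design.X1.shape[1], design.X2.shape[1]
    names = [f"y1:{n}" for n in design.names1] + [f"y2:{n}" for n in design.names2]
    bounds = [(None, None)] * (k1 + k2)
    if fix_alpha is None:
        names.append("alpha")
        bounds.append((-12.0, 12.0))
    n_sigma_par = 0
    if not sigma_fixed:
        n_sigma_par = {"shared": 1, "independent": 2, "correlated": 3}[re_structure]
        names += {"shared": ["log_sigma"],
                  "independent": ["log_sigma1", "log_sigma2"],
                  "correlated": ["log_sigma1", "log_sigma2", "atanh_rho"],
                  }[re_structure][:n_sigma_par]
        bounds += [(-10.0, 3.0)] * min(n_sigma_par, 2)
        if re_structure == "correlated":
            bounds[-1] = (-10.0, 3.0)
            bounds.append((-6.0, 6.0))

    def unpack(theta) -> Parameters:
        pos = k1 + k2
        beta1 = theta[:k1]
        beta2 = theta[k1:pos]
        if fix_alpha is None:
            alpha = float(theta[pos]); pos += 1
        else:
            alpha = float(fix_alpha)
        if sigma_fixed:
            sigma = fix_sigma_t
        elif re_structure == "shared":
            sigma = (float(np.exp(theta[pos])),)
        elif re_structure == "independent":
            sigma = (float(np.exp(theta[pos])), float(np.exp(theta[pos + 1])))
        else:
            sigma = (float(np.exp(theta[pos])), float(np.exp(theta[pos + 1])),
                     float(np.tanh(theta[pos + 2])))
        return Parameters(beta1.copy(), beta2.copy(), alpha, re_structure, sigma)

    # --- initialization: separate logistic fits, crude OR, moment sigma
    b1_0 = _irls(design.X1, y1, w)
    b2_0 = _irls(design.X2, y2, w)
    theta0 = list(b1_0) + list(b2_0)
    if fix_alpha is None:
        theta0.append(_crude_log_or(y1, y2))
    if not sigma_fixed:
        s0 = _sigma0(y1, y2, design.cluster_index, design.n_clusters)
        theta0.append(np.log(s0))
        if re_structure in ("independent", "correlated"):
            theta0.append(np.log(s0))
        if re_structure == "correlated":
            theta0.append(0.0)
    theta0 = np.asarray(theta0, float)

    cache = {"u": None}

    def negll(theta):
        params = unpack(np.asarray(theta, float))
        if _degenerate(params):
            ll = _fixed_effect_loglik(params, design, y1, y2, w)
        else:
            try:
                ll, u_hat, _ = _laplace_parts(params, design, y1, y2, w,
                                              u0=cache["u"])
                cache["u"] = u_hat
            except ConvergenceError:
                return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    res = optimize.minimize(
        negll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 10 * maxiter * max(1, len(theta0)),
                 "ftol": 1e-11, "gtol": 1e-6, "maxcor": 25})
    theta_hat = np.asarray(res.x, float)
    params_hat = unpack(theta_hat)
    loglik = -float(res.fun)
    grad_norm = float(np.max(np.abs(np.atleast_1d(res.jac))))
    converged = bool(res.success) or res.status == 0

    p_count = len(theta_hat)
    aic, bic = information_criteria(loglik, p_count, len(y1), design.n_clusters)

    se_vec = np.full(p_count, np.nan)
    ses_available = False
    if se:
        H = _numeric_hessian(negll, theta_hat)
        try:
            eig = np.linalg.eigvalsh(H)
            if np.all(eig > 0):
                cov = np.linalg.inv(H)
                diag = np.diag(cov)
                if np.all(diag > 0):
                    se_vec = np.sqrt(diag)
                    ses_available = True
        except np.linalg.LinAlgError:
            pass

    se_map = dict(zip(names, se_vec))
    aor = _aor_frame(design.names1, design.names2,
                     params_hat.beta1, params_hat.beta2, se_map)

    if re_structure == "shared":
        s2v = (params_hat.sigma[0] ** 2,)
        icc_d = {"y1": icc(s2v[0]), "y2": icc(s2v[0])}
    else:
        s2v = (params_hat.sigma[0] ** 2, params_hat.sigma[1] ** 2)
        icc_d = {"y1": icc(s2v[0]), "y2": icc(s2v[1])}

    association = None
    if fix_alpha is None:
        a = params_hat.alpha
        sa = se_map.get("alpha", float("nan"))
        zq = float(stats.norm.ppf(0.975))
        association = {
            "estimate": float(np.exp(a)),
            "log_or": float(a),
            "se_log": float(sa),
            "ci_low": float(np.exp(a - zq * sa)) if np.isfinite(sa) else None,
            "ci_high": float(np.exp(a + zq * sa)) if np.isfinite(sa) else None,
            "p": float(2 * stats.norm.sf(abs(a / sa)))
            if np.isfinite(sa) and sa > 0 else None,
        }

    return FitResult(
        params=params_hat, free_names=tuple(names), theta=theta_hat,
        se=se_vec, ses_available=ses_available, loglik=loglik,
        aic=aic, bic=bic, p_count=p_count, icc=icc_d, sigma2=s2v,
        association_or=association, aor_table=aor,
        n_units=len(y1), n_clusters=design.n_clusters,
        converged=converged, n_iter=int(res.nit), grad_norm=grad_norm,
        message=str(res.message), level_label=level.label, weighted=weighted,
    )


@dataclass
class LadderResult:
    """Null / individual / community / full model comparison."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)
    statuses: dict = field(default_factory=dict)

    @property
    def best_aic(self) -> str | None:
        ok = self.table.dropna(subset=["aic"])
        return None if ok.empty else str(ok.loc[ok["aic"].idxmin(), "model"])

    @property
    def best_bic(self) -> str | None:
        ok = self.table.dropna(subset=["bic"])
        return None if ok.empty else str(ok.loc[ok["bic"].idxmin(), "model"])


def model_ladder(table: AnalysisTable, individual_covs, community_covs,
                 schema=None, *, se: bool = False, **fit_options) -> LadderResult:
    """Fit the four-rung ladder and compare ICC / AIC / BIC.

    Null (intercepts only), individual covariates, community covariates,
    and the full model; a failing member is reported, not fatal.
    """
    individual = tuple(individual_covs)
    community = tuple(community_covs)
    levels = [
        ModelLevel("null", (), ()),
        ModelLevel("individual", individual, individual),
        ModelLevel("community", community, community),
        ModelLevel("full", individual + community, individual + community),
    ]
    rows, fits, statuses = [], {}, {}
    for lev in levels:
        try:
            r = fit(lev, table, schema, se=se, **fit_options)
            fits[lev.label] = r
            statuses[lev.label] = "ok" if r.converged else "not converged"
            rows.append({
                "model": lev.label, "p_count": r.p_count,
                "loglik": r.loglik, "icc": r.icc["y1"],
                "aic": r.aic, "bic": r.bic, "status": statuses[lev.label],
            })
        except Exception as exc:  # noqa: BLE001 - per-model status reporting
            statuses[lev.label] = f"failed: {exc}"
            rows.append({
                "model": lev.label, "p_count": np.nan, "loglik": np.nan,
                "icc": np.nan, "aic": np.nan, "bic": np.nan,
                "status": statuses[lev.label],
            })
    out = pd.DataFrame(rows)
    out["best_aic"] = out["model"] == LadderResult(out).best_aic
    return LadderResult(out, fits, statuses)
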