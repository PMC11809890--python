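"""Bivariate two-level logistic model: predictors and conditional likelihood.

Each woman contributes a pair of binary outcomes.  Conditional on her
zone's random effect(s) ``u``, the marginal success probabilities are
inverse-logits of linear predictors

    eta1 = X1 beta1 + u1[zone],    eta2 = X2 beta2 + u2[zone]

and the joint cell probabilities are the Plackett table with those margins
and a constant cell odds ratio ``psi = exp(alpha)`` — i.e. the association
is specified on the conditional (within-zone) scale.  The outcome pair is
a single multinomial draw over the four cells, so a unit's log-likelihood
is the log of the cell selected by its observed pair.

Random-effect structures:

``shared``
    one zonal intercept entering both predictors, scale ``sigma`` (the
    default: one latent intercept, hence a single ICC for both outcomes);
``independent``
    separate zonal intercepts per outcome, scales ``(sigma1, sigma2)``;
``correlated``
    bivariate normal intercepts ``(sigma1, sigma2, rho)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data_model import AnalysisTable, DesignMatrices
from .plackett import CellProbs, plackett_cells

__all__ = [
    "LOGISTIC_RESIDUAL_VARIANCE",
    "RE_STRUCTURES",
    "Parameters",
    "ModelLevel",
    "linear_predictors",
    "conditional_cells",
    "unit_loglik",
    "unit_loglik_and_grads",
    "cluster_conditional_loglik",
    "log_re_density",
]

#: variance of the standard-logistic level-1 residual, pi^2 / 3.
LOGISTIC_RESIDUAL_VARIANCE = np.pi ** 2 / 3.0

RE_STRUCTURES = ("shared", "independent", "correlated")

_MARGIN_EPS = 1e-12
_CELL_FLOOR = 1e-300


@dataclass
class Parameters:
    """Model parameters on the estimation scale.

    ``beta1``/``beta2`` are log-odds coefficient vectors aligned with the
    design matrices; ``alpha`` is the log cell odds ratio; ``sigma`` holds
    the random-effect scale(s) for the declared structure (see module
    docstring).
    """

    beta1: np.ndarray
    beta2: np.ndarray
    alpha: float = 0.0
    re_structure: str = "shared"
    sigma: tuple = (0.0,)

    def __post_init__(self):
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        if self.re_structure not in RE_STRUCTURES:
            raise ValueError(f"unknown random-effect structure {self.re_structure!r}")
        need = {"shared": 1, "independent": 2, "correlated": 3}[self.re_structure]
        if len(self.sigma) != need:
            raise ValueError(
                f"{self.re_structure} structure needs {need} sigma value(s)")
        if any(s < 0 for s in self.sigma[:2]) or (
                len(self.sigma) == 1 and self.sigma[0] < 0):
            raise ValueError("random-effect scale must be nonnegative")
        if self.re_structure == "correlated" and abs(self.sigma[2]) > 1:
            raise ValueError("|rho| must be <= 1")

    @property
    def psi(self) -> float:
        return float(np.exp(self.alpha))

    @property
    def re_dim(self) -> int:
        return 1 if self.re_structure == "shared" else 2

    def validate_against(self, design: DesignMatrices) -> None:
        if self.beta1.shape != (design.X1.shape[1],):
            raise ValueError("beta1 does not match X1 columns")
        if self.beta2.shape != (design.X2.shape[1],):
            raise ValueError("beta2 does not match X2 columns")

    def to_dict(self) -> dict:
        return {
            "beta1": self.beta1.tolist(),
            "beta2": self.beta2.tolist(),
            "alpha": float(self.alpha),
            "re_structure": self.re_structure,
            "sigma": list(self.sigma),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        return cls(np.asarray(d["beta1"], float), np.asarray(d["beta2"], float),
                   float(d["alpha"]), d["re_structure"], tuple(d["sigma"]))


@dataclass
class ModelLevel:
    """Covariate sets for one rung of the model ladder."""

    label: str
    covariates1: tuple[str, ...] = field(default_factory=tuple)
    covariates2: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.covariates1 = tuple(self.covariates1)
        self.covariates2 = tuple(self.covariates2)


def _u_columns(params: Parameters, u: np.ndarray):
    u = np.asarray(u, dtype=float)
    if params.re_structure == "shared":
        if u.ndim == 2:
            u = u[:, 0]
        return u, u
    if u.ndim != 2 or u.shape[1] != 2:
        raise ValueError("non-shared structures need a (clusters, 2) effect array")
    return u[:, 0], u[:, 1]


def linear_predictors(params: Parameters, design: DesignMatrices,
                      u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit linear predictors given cluster effects ``u``."""
    params.validate_against(design)
    u1, u2 = _u_columns(params, u)
    if len(u1) != design.n_clusters:
        raise ValueError("one effect (row) per cluster required")
    idx = design.cluster_index
    eta1 = design.X1 @ params.beta1 + u1[idx]
    eta2 = design.X2 @ params.beta2 + u2[idx]
    return eta1, eta2


def conditional_cells(params: Parameters, design: DesignMatrices,
                      u: np.ndarray) -> CellProbs:
    """Joint cell probabilities for every unit, conditional on ``u``."""
    eta1, eta2 = linear_predictors(params, design, u)
    p1 = np.clip(expit(eta1), _MARGIN_EPS, 1.0 - _MARGIN_EPS)
    p2 = np.clip(expit(eta2), _MARGIN_EPS, 1.0 - _MARGIN_EPS)
    return plackett_cells(p1, p2, params.psi)


def _select_cell(y1, y2, cells: CellProbs) -> np.ndarray:
    stacked = cells.as_array()                      # (..., 4) order 11,10,01,00
    idx = ((1 - np.asarray(y1)) * 2 + (1 - np.asarray(y2))).astype(np.int64)
    return np.take_along_axis(stacked, idx[..., None], axis=-1)[..., 0]


def unit_loglik(y1, y2, cells: CellProbs) -> np.ndarray | float:
    """Log of the multinomial cell selected by the observed outcome pair.

    A nonpositive selected cell yields ``-inf`` (flagged by the caller's
    optimizer rather than raising mid-likelihood).
    """
    sel = _select_cell(np.asarray(y1), np.asarray(y2), cells)
    with np.errstate(divide="ignore"):
        out = np.log(np.maximum(sel, _CELL_FLOOR))
    out = np.where(sel <= 0.0, -np.inf, out)
    if out.ndim == 0:
        return float(out)
    return out


def unit_loglik_and_grads(y1, y2, eta1, eta2, psi):
    """Per-unit log cell probability and its gradient in (eta1, eta2).

    Uses the implicit derivatives of the Plackett cell through the margins:
    with ``D = p11 + p00 + psi (p10 + p01)``,

        d p11 / d p1 = (p11 + psi p01) / D,
        d p11 / d p2 = (p11 + psi p10) / D,

    the other cells following by margin subtraction.  Returns
    ``(logp, dlogp/deta1, dlogp/deta2)`` as arrays.
    """
    p1 = np.clip(expit(eta1), _MARGIN_EPS, 1.0 - _MARGIN_EPS)
    p2 = np.clip(expit(eta2), _MARGIN_EPS, 1.0 - _MARGIN_EPS)
    cells = plackett_cells(p1, p2, psi)
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    sel = _select_cell(y1, y2, cells)
    with np.errstate(divide="ignore"):
        logp = np.log(np.maximum(sel, _CELL_FLOOR))

    D = cells.p11 + cells.p00 + psi * (cells.p10 + cells.p01)
    s1 = (cells.p11 + psi * cells.p01) / D          # d p11 / d p1
    s2 = (cells.p11 + psi * cells.p10) / D          # d p11 / d p2
    # d(selected cell)/dp1 and /dp2 by the outcome pair:
    #   cell 11: ( s1,  s2); 10: (1-s1, -s2); 01: (-s1, 1-s2); 00: (s1-1, s2-1)
    d_dp1 = np.where(y1 == 1, np.where(y2 == 1, s1, 1.0 - s1),
                     np.where(y2 == 1, -s1, s1 - 1.0))
    d_dp2 = np.where(y2 == 1, np.where(y1 == 1, s2, 1.0 - s2),
                     np.where(y1 == 1, -s2, s2 - 1.0))
    sel_safe = np.maximum(sel, _CELL_FLOOR)
    g1 = d_dp1 * p1 * (1.0 - p1) / sel_safe
    g2 = d_dp2 * p2 * (1.0 - p2) / sel_safe
    return logp, g1, g2


def log_re_density(params: Parameters, u: np.ndarray) -> np.ndarray:
    """Log density of the cluster effect(s) under the declared structure.

    Shared: ``u`` is (C,).  Otherwise ``u`` is (C, 2).  Returns one value
    per cluster.  Scales of exactly zero are degenerate and not valid here
    (the estimation layer short-circuits that case before integrating).
    """
    if params.re_structure == "shared":
        s = params.sigma[0]
        u = np.asarray(u, float)
        if u.ndim == 2:
            u = u[:, 0]
        return -0.5 * (u / s) ** 2 - 0.5 * np.log(2.0 * np.pi * s * s)
    u = np.asarray(u, float)
    s1, s2 = params.sigma[0], params.sigma[1]
    if params.re_structure == "independent":
        return (-0.5 * (u[:, 0] / s1) ** 2 - 0.5 * np.log(2 * np.pi * s1 * s1)
                - 0.5 * (u[:, 1] / s2) ** 2 - 0.5 * np.log(2 * np.pi * s2 * s2))
    rho = params.sigma[2]
    det = (s1 * s2) ** 2 * (1.0 - rho ** 2)
    z1 = u[:, 0] / s1
    z2 = u[:, 1] / s2
    quad = (z1 ** 2 - 2.0 * rho * z1 * z2 + z2 ** 2) / (1.0 - rho ** 2)
    return -0.5 * quad - 0.5 * np.log((2.0 * np.pi) ** 2 * det)


def cluster_conditional_loglik(params: Parameters, design: DesignMatrices,
                               table: AnalysisTable, cluster_id: str,
                               u, weighted: bool = False) -> float:
    """Joint log-likelihood of one cluster's units at effect value ``u``,
    plus the log density of ``u`` under the random-effect distribution.

    This is the integrand of the marginal likelihood.  With ``weighted``
    the unit weights multiply each unit's log-likelihood term
    (pseudo-likelihood); the prior part is never weighted.
    """
    try:
        c = design.cluster_ids.index(str(cluster_id))
    except ValueError:
        raise KeyError(f"cluster {cluster_id!r} not in design") from None
    rows = design.row_index[design.cluster_index == c]
    y1 = table.data["y1"].to_numpy()[rows]
    y2 = table.data["y2"].to_numpy()[rows]
    w = table.data["weight"].to_numpy(float)[rows] if weighted else np.ones(len(rows))

    u = np.atleast_1d(np.asarray(u, dtype=float))
    if params.re_structure == "shared":
        eta1 = design.X1[design.cluster_index == c] @ params.beta1 + u[0]
        eta2 = design.X2[design.cluster_index == c] @ params.beta2 + u[0]
        u_full = np.array([u[0]])
    else:
        eta1 = design.X1[design.cluster_index == c] @ params.beta1 + u[0]
        eta2 = design.X2[design.cluster_index == c] @ params.beta2 + u[1]
        u_full = u.reshape(1, 2)
    logp, _, _ = unit_loglik_and_grads(y1, y2, eta1, eta2, params.psi)
    degenerate = all(s == 0 for s in params.sigma[:2]) if \
        params.re_structure != "shared" else params.sigma[0] == 0
    prior = 0.0 if degenerate else float(log_re_density(params, u_full)[0])
    return float((w * logp).sum()) + prior
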