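"""Plackett (global odds-ratio) coupling of two Bernoulli margins.

A pair of binary outcomes with success probabilities ``p1`` and ``p2`` and a
cell odds ratio ``psi = p11*p00 / (p10*p01)`` has a *unique* joint 2x2
distribution.  This module maps ``(p1, p2, psi)`` to the four joint cell
probabilities and back.  ``psi = 1`` is independence; ``psi -> 0`` and
``psi -> inf`` approach the Frechet lower and upper bounds on ``p11``.

All functions are pure and accept scalars or NumPy arrays (broadcast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellProbs",
    "plackett_cells",
    "cells_near_independence",
    "cell_odds_ratio",
    "PSI_SWITCH",
]

#: half-width of the |psi - 1| window in which the series branch is used
#: (the quadratic formula loses digits to cancellation as psi -> 1).
PSI_SWITCH = 1e-6


@dataclass(frozen=True)
class CellProbs:
    """Joint probabilities of a 2x2 outcome table.

    ``p11`` is P(Y1=1, Y2=1), ``p10`` is P(Y1=1, Y2=0), and so on.  Fields
    may be scalars or arrays of a common shape.
    """

    p11: np.ndarray | float
    p10: np.ndarray | float
    p01: np.ndarray | float
    p00: np.ndarray | float

    def as_array(self) -> np.ndarray:
        """Stack the cells along a trailing axis, order (11, 10, 01, 00)."""
        return np.stack(
            [np.asarray(self.p11), np.asarray(self.p10),
             np.asarray(self.p01), np.asarray(self.p00)], axis=-1)

    @property
    def margin1(self) -> np.ndarray | float:
        """P(Y1 = 1)."""
        return self.p11 + self.p10

    @property
    def margin2(self) -> np.ndarray | float:
        """P(Y2 = 1)."""
        return self.p11 + self.p01


def _check_inputs(p1, p2, psi):
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.any(psi <= 0.0) or not np.all(np.isfinite(psi)):
        raise ValueError("odds ratio psi must be positive and finite")
    for name, p in (("p1", p1), ("p2", p2)):
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise ValueError(
                f"margin {name} must lie strictly inside (0, 1); "
                "degenerate margins have no two-parameter joint")
    return p1, p2, psi


def _p11_series(p1, p2, t):
    """Second-order expansion of p11 in t = psi - 1 around independence."""
    q1 = 1.0 - p1
    q2 = 1.0 - p2
    c1 = p1 * p2 * q1 * q2
    c2 = -c1 * ((p1 * q2 + p2 * q1) + 2.0 * c1)
    return p1 * p2 + t * (c1 + t * c2)


def _p11_solve(p1, p2, psi):
    """p11 with margins (p1, p2) and cell odds ratio psi.

    Quadratic-formula "-" root with a = 1 + (p1+p2)(psi-1), switching to a
    series branch near psi = 1, then two Newton polish steps on the defining
    equation p11*p00 - psi*p10*p01 = 0 so both branches land on the root to
    machine precision (this also guarantees continuity across the switch).
    """
    t = psi - 1.0
    near = np.abs(t) < PSI_SWITCH
    ts = np.where(near, 1.0, t)  # dummy divisor where the series is used
    a = 1.0 + (p1 + p2) * ts
    disc = a * a - 4.0 * psi * ts * p1 * p2
    quad = (a - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * ts)
    p11 = np.where(near, _p11_series(p1, p2, t), quad)

    lo = np.maximum(0.0, p1 + p2 - 1.0)
    hi = np.minimum(p1, p2)
    p11 = np.clip(p11, lo, hi)
    for _ in range(2):
        p10 = p1 - p11
        p01 = p2 - p11
        p00 = 1.0 - p1 - p2 + p11
        f = p11 * p00 - psi * p10 * p01
        fp = p00 + p11 + psi * (p10 + p01)  # > 0 on the Frechet interval
        p11 = np.clip(p11 - f / np.maximum(fp, 1e-300), lo, hi)
    return p11


def plackett_cells(p1, p2, psi) -> CellProbs:
    """Joint cell probabilities from margins and a cell odds ratio.

    Parameters
    ----------
    p1, p2 : float or array
        Success probabilities of the two binary outcomes, in (0, 1).
    psi : float or array
        Cell odds ratio, > 0.  ``psi = 1`` gives the independence table.

    Returns
    -------
    CellProbs
        The unique table with the requested margins and odds ratio; margins
        are conserved exactly (``p10``/``p01``/``p00`` by subtraction).
    """
    p1, p2, psi = _check_inputs(p1, p2, psi)
    p1b, p2b, psib = np.broadcast_arrays(p1, p2, psi)
    p11 = _p11_solve(p1b.astype(float), p2b.astype(float), psib.astype(float))
    p10 = p1b - p11
    p01 = p2b - p11
    p00 = 1.0 - p1b - p2b + p11
    if p11.ndim == 0:
        return CellProbs(float(p11), float(p10), float(p01), float(p00))
    return CellProbs(p11, p10, p01, p00)


def cells_near_independence(p1, p2, psi) -> CellProbs:
    """Cancellation-free evaluation of :func:`plackett_cells` for psi near 1.

    Uses the series expansion around independence followed by Newton polish;
    agrees with the general branch to well below 1e-12 at the switching
    threshold (both branches are polished onto the same root), and returns
    the exact product table at ``psi = 1``.
    """
    p1, p2, psi = _check_inputs(p1, p2, psi)
    p1b, p2b, psib = np.broadcast_arrays(
        np.asarray(p1, float), np.asarray(p2, float), np.asarray(psi, float))
    t = psib - 1.0
    p11 = _p11_series(p1b, p2b, t)
    lo = np.maximum(0.0, p1b + p2b - 1.0)
    hi = np.minimum(p1b, p2b)
    p11 = np.clip(p11, lo, hi)
    for _ in range(2):
        p10 = p1b - p11
        p01 = p2b - p11
        p00 = 1.0 - p1b - p2b + p11
        f = p11 * p00 - psib * p10 * p01
        fp = p00 + p11 + psib * (p10 + p01)
        p11 = np.clip(p11 - f / np.maximum(fp, 1e-300), lo, hi)
    p10 = p1b - p11
    p01 = p2b - p11
    p00 = 1.0 - p1b - p2b + p11
    if p11.ndim == 0:
        return CellProbs(float(p11), float(p10), float(p01), float(p00))
    return CellProbs(p11, p10, p01, p00)


def cell_odds_ratio(cells: CellProbs) -> np.ndarray | float:
    """Cell odds ratio ``p11*p00 / (p10*p01)`` of a joint table.

    A zero off-diagonal cell yields ``inf`` explicitly (the association is
    at the Frechet boundary) rather than raising.
    """
    num = np.asarray(cells.p11, float) * np.asarray(cells.p00, float)
    den = np.asarray(cells.p10, float) * np.asarray(cells.p01, float)
    with np.errstate(divide="ignore"):
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), np.inf)
    if out.ndim == 0:
        return float(out)
    return out
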