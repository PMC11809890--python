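"""Survey-weighted descriptive layer for the two maternal-care outcomes.

Weighted frequency tables, covariate-by-outcome cross-tabulations with
Pearson chi-square tests, the joint 2x2 outcome table with its odds ratio
and Woolf confidence interval, and four-category joint risk profiles
(outcome-combination frequencies per covariate level).

All counts are weighted; chi-square tests are applied to the weighted
counts directly (design-naive, no Rao-Scott correction — documented as a
limitation of the approach being reproduced).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import MISSING_LEVEL, AnalysisTable

__all__ = [
    "JointTable2x2",
    "ORResult",
    "CrossTab",
    "weighted_frequency",
    "crosstab_chisq",
    "joint_outcome_table",
    "contingency_odds_ratio",
    "joint_risk_profile",
]

_OUTCOME_LEVELS = {"y1": (0, 1), "y2": (0, 1)}


def _levels_for(table: AnalysisTable, variable: str):
    """Declared level order for a covariate, 0/1 for an outcome."""
    if variable in _OUTCOME_LEVELS:
        return list(_OUTCOME_LEVELS[variable])
    spec = table.spec(variable)
    levels = list(spec.levels)
    if (table.data[variable] == MISSING_LEVEL).any():
        levels.append(MISSING_LEVEL)
    return levels


def weighted_frequency(table: AnalysisTable, variable: str) -> pd.DataFrame:
    """Weighted counts and percentages of one variable's levels.

    Returns a frame with columns ``level``, ``count``, ``percent``;
    percentages sum to 100 (up to rounding).
    """
    df = table.data
    if variable not in df.columns:
        raise KeyError(f"variable {variable!r} not in table")
    w = df["weight"].to_numpy(float)
    levels = _levels_for(table, variable)
    counts = [float(w[df[variable].to_numpy() == lev].sum()) for lev in levels]
    total = sum(counts)
    pct = [100.0 * c / total if total > 0 else np.nan for c in counts]
    return pd.DataFrame({"level": levels, "count": counts, "percent": pct})


@dataclass
class CrossTab:
    """Weighted covariate-by-outcome cross-tab with a Pearson chi-square test."""

    covariate: str
    outcome: str
    counts: pd.DataFrame       # rows: covariate levels; columns: outcome levels
    row_percent: pd.DataFrame
    chi2: float
    df: int
    pvalue: float
    zero_expected: bool = False


def crosstab_chisq(table: AnalysisTable, covariate: str, outcome: str) -> CrossTab:
    """Pearson chi-square on the weighted covariate x outcome table.

    ``X^2 = sum (O - E)^2 / E`` with expectations from the row/column
    margins and a chi-square reference distribution on ``(r-1)(c-1)``
    degrees of freedom.  A zero expected cell is skipped in the sum and
    flagged with a warning (the statistic is still returned).
    """
    df = table.data
    w = df["weight"].to_numpy(float)
    rows = _levels_for(table, covariate)
    cols = _levels_for(table, outcome)
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("need at least 2 observed levels on each axis")
    O = np.zeros((len(rows), len(cols)))
    cov_vals = df[covariate].to_numpy()
    out_vals = df[outcome].to_numpy()
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            O[i, j] = w[(cov_vals == r) & (out_vals == c)].sum()
    total = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    zero_expected = bool((E == 0).any())
    if zero_expected:
        warnings.warn(
            f"zero expected cell in {covariate} x {outcome} cross-tab; "
            "those cells are skipped in the chi-square sum", stacklevel=2)
    mask = E > 0
    chi2 = float(((O[mask] - E[mask]) ** 2 / E[mask]).sum())
    ddof = (len(rows) - 1) * (len(cols) - 1)
    pvalue = float(stats.chi2.sf(chi2, ddof))
    counts = pd.DataFrame(O, index=rows, columns=cols)
    row_percent = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return CrossTab(covariate, outcome, counts, row_percent,
                    chi2, ddof, pvalue, zero_expected)


@dataclass
class JointTable2x2:
    """Weighted joint 2x2 table of the two outcomes.

    ``n11`` counts units with both outcomes 1 (adequate ANC *and* facility
    delivery), ``n10`` ANC-only, ``n01`` facility-only, ``n00`` neither.
    """

    n11: float
    n10: float
    n01: float
    n00: float

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def margin_y1(self) -> tuple[float, float]:
        """(Y1=1 total, Y1=0 total)."""
        return (self.n11 + self.n10, self.n01 + self.n00)

    @property
    def margin_y2(self) -> tuple[float, float]:
        """(Y2=1 total, Y2=0 total)."""
        return (self.n11 + self.n01, self.n10 + self.n00)

    def proportions(self) -> dict:
        """Joint proportions (count / grand total); NaN-flagged if empty."""
        t = self.total
        if t <= 0:
            return {k: float("nan") for k in ("p11", "p10", "p01", "p00")}
        return {"p11": self.n11 / t, "p10": self.n10 / t,
                "p01": self.n01 / t, "p00": self.n00 / t}

    def swapped_columns(self) -> "JointTable2x2":
        """Swap the Y2 columns (used by the OR-inversion invariant)."""
        return JointTable2x2(self.n10, self.n11, self.n00, self.n01)


def joint_outcome_table(table: AnalysisTable) -> JointTable2x2:
    """Weighted joint counts of the two binary outcomes."""
    df = table.data
    w = df["weight"].to_numpy(float)
    y1 = df["y1"].to_numpy()
    y2 = df["y2"].to_numpy()
    return JointTable2x2(
        n11=float(w[(y1 == 1) & (y2 == 1)].sum()),
        n10=float(w[(y1 == 1) & (y2 == 0)].sum()),
        n01=float(w[(y1 == 0) & (y2 == 1)].sum()),
        n00=float(w[(y1 == 0) & (y2 == 0)].sum()),
    )


@dataclass
class ORResult:
    """2x2 odds ratio with a Woolf (log-scale normal) confidence interval."""

    or_hat: float
    ci_low: float
    ci_high: float
    level: float
    se_log: float


def contingency_odds_ratio(t: JointTable2x2, level: float = 0.95,
                           continuity: bool = False) -> ORResult:
    """Cross-product odds ratio ``(n11*n00)/(n10*n01)`` with Woolf CI.

    The CI is ``exp(ln OR +/- z * sqrt(1/n11 + 1/n10 + 1/n01 + 1/n00))``
    with ``z`` the standard-normal quantile for the confidence level.
    Zero cells raise unless ``continuity=True`` (Haldane-Anscombe +0.5 on
    every cell, off by default).
    """
    cells = {"n11": t.n11, "n10": t.n10, "n01": t.n01, "n00": t.n00}
    if continuity:
        cells = {k: v + 0.5 for k, v in cells.items()}
    for name, v in cells.items():
        if v <= 0:
            raise ValueError(
                f"cell {name} is zero; pass continuity=True for the "
                "Haldane-Anscombe correction")
    or_hat = (cells["n11"] * cells["n00"]) / (cells["n10"] * cells["n01"])
    se_log = float(np.sqrt(sum(1.0 / v for v in cells.values())))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    log_or = float(np.log(or_hat))
    return ORResult(
        or_hat=float(or_hat),
        ci_low=float(np.exp(log_or - z * se_log)),
        ci_high=float(np.exp(log_or + z * se_log)),
        level=level,
        se_log=se_log,
    )


def joint_risk_profile(table: AnalysisTable, covariate: str) -> pd.DataFrame:
    """Four-way outcome-combination frequencies per covariate level.

    Per level of the covariate: weighted counts of the combinations
    (no-ANC & home, no-ANC & facility, ANC & home, ANC & facility) and row
    percentages normalized *within* each ANC stratum (the no-ANC pair sums
    to 100, as does the ANC pair), matching the survey-report layout.
    """
    df = table.data
    w = df["weight"].to_numpy(float)
    y1 = df["y1"].to_numpy()
    y2 = df["y2"].to_numpy()
    vals = df[covariate].to_numpy()
    rows = []
    for lev in _levels_for(table, covariate):
        m = vals == lev
        n00 = float(w[m & (y1 == 0) & (y2 == 0)].sum())  # no ANC, home
        n01 = float(w[m & (y1 == 0) & (y2 == 1)].sum())  # no ANC, facility
        n10 = float(w[m & (y1 == 1) & (y2 == 0)].sum())  # ANC, home
        n11 = float(w[m & (y1 == 1) & (y2 == 1)].sum())  # ANC, facility
        no_anc = n00 + n01
        anc = n10 + n11
        rows.append({
            "level": lev,
            "no_anc_home": n00,
            "no_anc_facility": n01,
            "anc_home": n10,
            "anc_facility": n11,
            "pct_no_anc_home": 100.0 * n00 / no_anc if no_anc > 0 else np.nan,
            "pct_no_anc_facility": 100.0 * n01 / no_anc if no_anc > 0 else np.nan,
            "pct_anc_home": 100.0 * n10 / anc if anc > 0 else np.nan,
            "pct_anc_facility": 100.0 * n11 / anc if anc > 0 else np.nan,
        })
    return pd.DataFrame(rows)
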