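"""Per-date treatment comparisons with Bonferroni control.

Shoot RER is compared between treatments with one-sided unpaired
Mann-Whitney tests, fruit RGR with one-sided Welch t-tests, one test per
shared measurement interval; raw p-values are Bonferroni-adjusted within
the comparison series and summarised with significance stars.  A linear
model assesses treatment and GDD effects on the relative increment in
trunk circumference.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .growth_analysis import DEFAULT_ALIGN_TOL, GrowthRateSeries, align_rate_series

logger = logging.getLogger(__name__)

#: total sample size up to which the Mann-Whitney p is computed by exact
#: enumeration of arrangements (ties force the corrected normal approximation)
EXACT_MW_LIMIT = 16

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def mann_whitney_one_sided(
    a, b, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided unpaired Mann-Whitney test; returns (U of sample a, p).

    ``alternative="greater"`` tests whether ``a`` tends larger than ``b``.
    The p-value is exact (full enumeration of rank arrangements) when
    ``len(a)+len(b) <= 16`` and there are no ties, otherwise the
    tie-corrected normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def t_test_one_sided(a, b, alternative: str = "greater") -> tuple[float, float]:
    """One-sided unpaired Welch t-test; returns (t, p).

    ``alternative="greater"`` tests whether the mean of ``a`` exceeds that
    of ``b``.  Two zero-variance samples with equal means carry no
    one-sided evidence: that degenerate case returns (0, 0.5) with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups with equal means; p = 0.5")
            return 0.0, 0.5
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: each p times the family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def stars(adjusted_p: float) -> str:
    """Significance stars: *** <= 0.001, ** <= 0.01, * <= 0.05."""
    if not 0.0 <= adjusted_p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    for threshold, mark in STAR_THRESHOLDS:
        if adjusted_p <= threshold:
            return mark
    return ""


def compare_series(
    series_a: list[GrowthRateSeries],
    series_b: list[GrowthRateSeries],
    test_kind: str = "mann_whitney",
    alternative: str = "greater",
    align_tol: float = DEFAULT_ALIGN_TOL,
) -> pd.DataFrame:
    """Per-interval one-sided tests between two groups of rate series.

    Intervals are matched by index; interval midpoints of the two groups
    must agree within ``align_tol`` GDD.  The Bonferroni family is the
    number of shared intervals.  ``alternative="greater"`` tests group A >
    group B at each interval.

    Returns a frame with ``gdd_mid, n_a, n_b, statistic, raw_p, adj_p,
    stars``.
    """
    if test_kind not in ("mann_whitney", "t_test"):
        raise ValueError(f"unknown test_kind {test_kind!r}")
    series_a = [s for s in series_a if len(s) > 0]
    series_b = [s for s in series_b if len(s) > 0]
    if not series_a or not series_b:
        raise ValueError("both groups need at least one non-empty rate series")
    grid, indices = align_rate_series(series_a + series_b, align_tol)
    cells_a: list[list[float]] = [[] for _ in grid]
    cells_b: list[list[float]] = [[] for _ in grid]
    for s, idx, cells in (
        [(s, i, cells_a) for s, i in zip(series_a, indices[: len(series_a)])]
        + [(s, i, cells_b) for s, i in zip(series_b, indices[len(series_a):])]
    ):
        for i, r in zip(idx, s.rates):
            cells[i].append(r)
    min_n = 1 if test_kind == "mann_whitney" else 2
    test = mann_whitney_one_sided if test_kind == "mann_whitney" else t_test_one_sided
    rows = []
    for g, va, vb in zip(grid, cells_a, cells_b):
        if len(va) < min_n or len(vb) < min_n:
            continue
        va, vb = np.asarray(va), np.asarray(vb)
        stat, p = test(va, vb, alternative)
        rows.append(
            {
                "gdd_mid": g,
                "n_a": va.size,
                "n_b": vb.size,
                "statistic": stat,
                "raw_p": p,
            }
        )
    if not rows:
        raise ValueError("no shared intervals between the groups")
    table = pd.DataFrame(rows)
    table["adj_p"] = bonferroni(table["raw_p"].to_numpy())
    table["stars"] = [stars(p) for p in table["adj_p"]]
    table.attrs["test_kind"] = test_kind
    table.attrs["alternative"] = alternative
    return table


@dataclass
class LinearModelReport:
    """Coefficient table of an OLS fit (terms, SEs, t, two-sided p)."""

    coefficients: pd.DataFrame  # index: term; columns coef, se, t, p
    n: int
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.round(10).to_dict(orient="index"),
            "n": self.n,
            "r_squared": self.r_squared,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def trunk_treatment_model(
    data: pd.DataFrame, include_interaction: bool = False
) -> LinearModelReport:
    """OLS of trunk relative increment on treatment (categorical) and GDD.

    ``data`` needs columns ``relative_increment``, ``treatment``, ``gdd``
    (one row per tree and date), >= 2 treatment levels and >= 3 distinct
    GDD values.
    """
    required = {"relative_increment", "treatment", "gdd"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    levels = sorted(data["treatment"].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 treatment levels")
    if data["gdd"].nunique() < 3:
        raise ValueError("need >= 3 distinct GDD values")
    y = data["relative_increment"].to_numpy(dtype=float)
    g = data["gdd"].to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    names = ["intercept"]
    dummies = []
    for lev in levels[1:]:
        d = (data["treatment"].astype(str) == lev).to_numpy(dtype=float)
        cols.append(d)
        names.append(f"treatment[{lev}]")
        dummies.append((lev, d))
    cols.append(g)
    names.append("gdd")
    if include_interaction:
        for lev, d in dummies:
            cols.append(d * g)
            names.append(f"treatment[{lev}]:gdd")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design among terms {names}")
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=names,
    )
    return LinearModelReport(
        coefficients=table, n=len(data), r_squared=float(res.rsquared)
    )


def density_comparison(densities_a, densities_b) -> tuple[float, float]:
    """One-sided Welch test of whether group A is denser than group B
    (e.g. defruited vs. fruited shoot wood density, g/cm^3)."""
    return t_test_one_sided(densities_a, densities_b, alternative="greater")
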