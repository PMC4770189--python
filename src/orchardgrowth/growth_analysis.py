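"""Relative growth rates on the thermal-time axis.

Classical growth analysis: for successive measurements ``x1`` at ``g1`` and
``x2`` at ``g2`` (GDD), the interval relative rate is
``(ln x2 - ln x1) / (g2 - g1)``, assigned to the interval midpoint.
Applied to length it is the relative elongation rate (RER), to dry mass the
relative growth rate (RGR); units are per degC day.  Trunk RGR comes from a
straight line fitted to log biomass vs. GDD; its slope is the RGR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SHOOT_CLASSES = ("proleptic", "epicormic", "unknown")

#: GDD slack when deciding whether two organs share a measurement schedule
DEFAULT_ALIGN_TOL = 1.0


@dataclass
class OrganTrajectory:
    """Repeated observations of one organ on the GDD axis.

    ``observations`` holds a ``gdd`` column (strictly increasing) and any of
    ``length`` (cm), ``dry_mass`` (g), ``circumference`` (mm); all recorded
    values must be positive.
    """

    organ_id: str
    tree_id: str
    treatment: str
    organ_type: str  # shoot | fruit | trunk
    observations: pd.DataFrame
    shoot_class: str = "unknown"
    canopy_level: str | None = None
    pest_damaged: bool = False
    pruning_trace: bool | None = None

    def __post_init__(self) -> None:
        obs = self.observations.reset_index(drop=True)
        if "gdd" not in obs.columns:
            raise ValueError("observations need a 'gdd' column")
        g = obs["gdd"].to_numpy(dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError(f"{self.organ_id}: observations must be strictly increasing in gdd")
        for col in ("length", "dry_mass", "circumference"):
            if col in obs.columns:
                v = obs[col].to_numpy(dtype=float)
                if np.any(v[np.isfinite(v)] <= 0):
                    raise ValueError(f"{self.organ_id}: non-positive {col}")
        self.observations = obs

    def values(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """(gdd, value) pairs where ``variable`` is present and finite."""
        if variable not in self.observations.columns:
            return np.empty(0), np.empty(0)
        mask = np.isfinite(self.observations[variable].to_numpy(dtype=float))
        sub = self.observations[mask]
        return (
            sub["gdd"].to_numpy(dtype=float),
            sub[variable].to_numpy(dtype=float),
        )

    @property
    def final_length(self) -> float | None:
        g, v = self.values("length")
        return float(v[-1]) if v.size else None

    @property
    def final_dry_mass(self) -> float | None:
        g, v = self.values("dry_mass")
        return float(v[-1]) if v.size else None


@dataclass
class GrowthRateSeries:
    """Interval relative rates for one organ, at interval-midpoint GDD."""

    organ_id: str
    rate_kind: str  # "RER" | "RGR"
    gdd_mid: np.ndarray
    rates: np.ndarray
    gdd_start: np.ndarray = field(default=None)
    gdd_end: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.gdd_mid = np.asarray(self.gdd_mid, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.gdd_start is None:
            self.gdd_start = np.full_like(self.gdd_mid, np.nan)
        if self.gdd_end is None:
            self.gdd_end = np.full_like(self.gdd_mid, np.nan)
        self.gdd_start = np.asarray(self.gdd_start, dtype=float)
        self.gdd_end = np.asarray(self.gdd_end, dtype=float)
        if np.any(np.diff(self.gdd_mid) <= 0):
            raise ValueError("gdd_mid must be strictly increasing")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")

    def __len__(self) -> int:
        return len(self.gdd_mid)


@dataclass
class LogLinearFit:
    """OLS line through (gdd, ln biomass); the slope is the RGR."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("log-linear fit needs at least 2 points")


def interval_relative_rate(x1: float, x2: float, g1: float, g2: float) -> float:
    """Relative rate over one interval: ``(ln x2 - ln x1)/(g2 - g1)``.

    Unit-invariant: rescaling both sizes by a common factor cancels.
    Negative values are legitimate (late-season fruit mass decline).
    """
    if g2 <= g1:
        raise ValueError("interval must have g2 > g1")
    if x1 <= 0 or x2 <= 0:
        raise ValueError("sizes must be positive")
    return (np.log(x2) - np.log(x1)) / (g2 - g1)


def trajectory_rates(traj: OrganTrajectory, variable: str) -> GrowthRateSeries:
    """Interval rates for every successive pair of observations.

    ``variable`` is ``"length"`` (-> RER) or ``"dry_mass"`` (-> RGR).
    Fewer than two usable observations yield an empty series with a warning.
    """
    if variable not in ("length", "dry_mass"):
        raise ValueError(f"unknown variable {variable!r}")
    kind = "RER" if variable == "length" else "RGR"
    g, x = traj.values(variable)
    if len(x) < 2:
        warnings.warn(f"{traj.organ_id}: <2 {variable} observations, empty rate series")
        return GrowthRateSeries(traj.organ_id, kind, np.empty(0), np.empty(0))
    rates = np.array(
        [interval_relative_rate(x[i], x[i + 1], g[i], g[i + 1]) for i in range(len(x) - 1)]
    )
    mids = 0.5 * (g[:-1] + g[1:])
    return GrowthRateSeries(
        traj.organ_id, kind, mids, rates, gdd_start=g[:-1], gdd_end=g[1:]
    )


def align_rate_series(
    series_set: list[GrowthRateSeries],
    align_tol: float = DEFAULT_ALIGN_TOL,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Map each series onto the shared interval grid of the cohort.

    The grid is the midpoint vector of the longest series; every point of
    every series must land within ``align_tol`` GDD of a grid cell (organs
    are measured on the same dates, so a series may *miss* intervals — e.g.
    masses below the model's resolution early on — but may not sit between
    them).  Returns the grid and, per series, the grid index of each point.

    Raises listing the offending organs when a series cannot be placed.
    """
    series_set = [s for s in series_set if len(s) > 0]
    if not series_set:
        return np.empty(0), []
    grid = max(series_set, key=len).gdd_mid
    indices: list[np.ndarray] = []
    misaligned: list[str] = []
    for s in series_set:
        right = np.clip(np.searchsorted(grid, s.gdd_mid), 0, len(grid) - 1)
        left = np.clip(right - 1, 0, len(grid) - 1)
        nearest = np.where(
            np.abs(grid[left] - s.gdd_mid) <= np.abs(grid[right] - s.gdd_mid),
            left,
            right,
        )
        if np.any(np.abs(grid[nearest] - s.gdd_mid) > align_tol) or np.any(
            np.diff(nearest) <= 0
        ):
            misaligned.append(s.organ_id)
        indices.append(nearest)
    if misaligned:
        raise ValueError(
            f"rate series not aligned with shared schedule (tol {align_tol} GDD): "
            f"{misaligned}"
        )
    return grid, indices


def mean_rate_curve(
    series_set: list[GrowthRateSeries],
    align_tol: float = DEFAULT_ALIGN_TOL,
) -> pd.DataFrame:
    """Per-interval mean and SD of rates across organs sharing a schedule.

    Returns a frame with ``gdd_mid, mean, sd, n`` (SD is 0 for n = 1);
    intervals with no organ at all are omitted.
    """
    series_set = [s for s in series_set if len(s) > 0]
    if not series_set:
        return pd.DataFrame(columns=["gdd_mid", "mean", "sd", "n"])
    grid, indices = align_rate_series(series_set, align_tol)
    cells: list[list[float]] = [[] for _ in grid]
    for s, idx in zip(series_set, indices):
        for i, r in zip(idx, s.rates):
            cells[i].append(r)
    rows = []
    for g, vals in zip(grid, cells):
        if not vals:
            continue
        arr = np.asarray(vals)
        rows.append(
            {
                "gdd_mid": g,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "n": len(arr),
            }
        )
    return pd.DataFrame(rows)


def fit_log_linear_rgr(gdd, log_biomass) -> LogLinearFit:
    """OLS fit of ln(biomass) on GDD; the slope is reported as RGR."""
    g = np.asarray(gdd, dtype=float)
    y = np.asarray(log_biomass, dtype=float)
    if len(g) < 2 or len(g) != len(y):
        raise ValueError("need >= 2 (gdd, log biomass) pairs")
    if np.ptp(g) == 0:
        raise ValueError("GDD values are all identical; cannot fit a line")
    with warnings.catch_warnings():
        # linregress warns on n=2 (r==1 exactly); that case is well-defined here
        warnings.simplefilter("ignore")
        res = stats.linregress(g, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return LogLinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=len(g),
    )


def treatment_log_biomass_means(
    trajectories: list[OrganTrajectory], variable: str = "dry_mass"
) -> pd.DataFrame:
    """Per-date mean of ln(biomass) across organs (trunk RGR default path)."""
    rows = []
    for traj in trajectories:
        g, v = traj.values(variable)
        for gi, vi in zip(g, v):
            rows.append({"gdd": gi, "log_mass": np.log(vi)})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["gdd", "mean_log_mass", "n"])
    out = (
        df.groupby("gdd")["log_mass"].agg(["mean", "count"]).reset_index()
    )
    out.columns = ["gdd", "mean_log_mass", "n"]
    return out


def normalized_circumference(traj: OrganTrajectory) -> pd.DataFrame:
    """Trunk circumference divided by its first observation.

    The first value is exactly 1; ``value - 1`` is the relative increment.
    """
    g, c = traj.values("circumference")
    if c.size == 0:
        raise ValueError(f"{traj.organ_id}: no circumference observations")
    return pd.DataFrame({"gdd": g, "normalized": c / c[0]})


def detect_elongation_cessation(
    series: GrowthRateSeries, threshold: float = 1e-2
) -> float | None:
    """First GDD midpoint from which RER stays below ``threshold``.

    The sub-threshold condition must hold for *all* remaining points
    (sustained plateau), so a single noisy dip does not register.  Returns
    None when elongation never ceases within the record.
    """
    if series.rate_kind != "RER":
        raise ValueError("cessation detection applies to RER series")
    if len(series) == 0:
        warnings.warn(f"{series.organ_id}: empty RER series")
        return None
    below = series.rates < threshold
    if not below[-1]:
        return None
    # walk back from the end while still below threshold
    i = len(below) - 1
    while i > 0 and below[i - 1]:
        i -= 1
    return float(series.gdd_mid[i])
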