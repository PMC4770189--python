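"""Maximum-potential-growth extraction.

Growth of organs freed from competition (defruited trees, heavily thinned
fruit) approximates sink-limited, i.e. maximum potential, growth.  Even so,
individual organs vary, so the extraction works on sub-populations:

* shoots shorter than 4 cm at season end are dropped as probable spurs;
* shoots on branches with pruning traces are classed epicormic, the rest
  proleptic; per class, the five shoots with the highest final dry mass
  represent the class's maximum potential RER/RGR;
* for the trunk, the single tree with the highest seasonal increment in
  normalized circumference (the "Max" tree);
* for fruit, the plain mean over non-pest-damaged thinned-tree fruits —
  fruit variability is dominated by fruit-set timing, not local resource
  limitation, which the two diagnostic regressions in
  :func:`fruit_variability_analysis` make visible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import WoodAllometryParams, wood_agb
from .growth_analysis import (
    GrowthRateSeries,
    LogLinearFit,
    OrganTrajectory,
    fit_log_linear_rgr,
    mean_rate_curve,
    normalized_circumference,
    trajectory_rates,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_FINAL_LENGTH = 4.0  # cm, strict: "longer than 4 cm"
DEFAULT_K_MAX_SHOOTS = 5


@dataclass
class MaxSelection:
    """Organs selected to represent maximum potential growth."""

    category: str  # proleptic | epicormic | trunk | fruit
    member_ids: list[str]
    selection_metric: dict  # organ_id -> final dry mass (g) or trunk increment
    rer_curve: pd.DataFrame | None = None  # gdd_mid, mean, sd, n
    rgr_curve: pd.DataFrame | None = None
    trunk_fit: LogLinearFit | None = None


@dataclass
class FruitVariabilityReport:
    """Diagnostics of fruit-weight variability on thinned trees.

    Regression A: harvest dry mass ~ first-date dry mass.
    Regression B: first-date dry mass ~ early-season (first-interval) RGR.
    A positive A-slope with a negative B-slope indicates the variability is
    driven by differential fruit-set timing rather than resource limitation.
    """

    slope_harvest_initial: float
    intercept_harvest_initial: float
    r2_harvest_initial: float
    p_harvest_initial: float
    slope_initial_early_rgr: float
    intercept_initial_early_rgr: float
    r2_initial_early_rgr: float
    p_initial_early_rgr: float
    n_fruits: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def filter_spurs(
    shoots: list[OrganTrajectory],
    min_final_length: float = DEFAULT_MIN_FINAL_LENGTH,
) -> list[OrganTrajectory]:
    """Drop shoots whose end-of-season length is not strictly above the
    threshold (default 4 cm); such shoots are probable spurs."""
    kept = [
        s
        for s in shoots
        if s.final_length is not None and s.final_length > min_final_length
    ]
    removed = len(shoots) - len(kept)
    logger.info(
        "spur filter: removed %d of %d shoots (final length <= %g cm)",
        removed,
        len(shoots),
        min_final_length,
    )
    if not kept:
        warnings.warn("spur filter removed every shoot")
    return kept


def classify_shoot_type(shoot: OrganTrajectory) -> str:
    """Epicormic if the bearing branch shows pruning traces, else proleptic.

    A missing flag classifies as ``unknown`` (excluded from Max-shoot
    selection) with a warning.
    """
    if shoot.pruning_trace is None:
        warnings.warn(f"{shoot.organ_id}: no pruning-trace flag; shoot class unknown")
        return "unknown"
    return "epicormic" if shoot.pruning_trace else "proleptic"


def classify_shoots(shoots: list[OrganTrajectory]) -> list[OrganTrajectory]:
    """Assign ``shoot_class`` in place on each trajectory; returns the list."""
    for s in shoots:
        s.shoot_class = classify_shoot_type(s)
    return shoots


def _selection_curves(
    members: list[OrganTrajectory],
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    rer = [trajectory_rates(s, "length") for s in members if s.values("length")[0].size >= 2]
    rgr = [trajectory_rates(s, "dry_mass") for s in members if s.values("dry_mass")[0].size >= 2]
    return (
        mean_rate_curve(rer) if rer else None,
        mean_rate_curve(rgr) if rgr else None,
    )


def select_max_shoots(
    shoots: list[OrganTrajectory],
    k: int = DEFAULT_K_MAX_SHOOTS,
) -> dict[str, MaxSelection]:
    """Per shoot class, the k shoots with the highest final dry mass.

    Input shoots should already be spur-filtered and classified (pooled
    across trees).  Ties at rank k break by final length, then organ id, so
    the selection is deterministic.  A class with fewer than k members is
    returned whole with a warning.
    """
    out: dict[str, MaxSelection] = {}
    for category in ("proleptic", "epicormic"):
        members = [
            s
            for s in shoots
            if s.shoot_class == category and s.final_dry_mass is not None
        ]
        ordered = sorted(
            members,
            key=lambda s: (-s.final_dry_mass, -(s.final_length or 0.0), s.organ_id),
        )
        if not ordered:
            warnings.warn(f"no {category} shoots available for Max selection")
            out[category] = MaxSelection(category, [], {})
            continue
        if len(ordered) < k:
            warnings.warn(
                f"only {len(ordered)} {category} shoot(s) available (k={k}); using all"
            )
        top = ordered[:k]
        rer_curve, rgr_curve = _selection_curves(top)
        out[category] = MaxSelection(
            category=category,
            member_ids=[s.organ_id for s in top],
            selection_metric={s.organ_id: s.final_dry_mass for s in top},
            rer_curve=rer_curve,
            rgr_curve=rgr_curve,
        )
    return out


def select_max_trunk(
    trees: list[OrganTrajectory],
    wood_params: WoodAllometryParams | None = None,
) -> MaxSelection:
    """The tree with the highest final increment in normalized trunk
    circumference; its log-linear woody-biomass RGR fit is attached.

    Circumference observations are in mm; the wood allometry expects cm.
    """
    eligible = []
    for t in trees:
        g, c = t.values("circumference")
        if c.size >= 2:
            eligible.append((t, g, c))
    if not eligible:
        raise ValueError("no tree with >= 2 circumference observations")
    increments = {}
    best = None
    for t, g, c in eligible:
        norm = normalized_circumference(t)
        inc = float(norm["normalized"].iloc[-1] - 1.0)
        increments[t.organ_id] = inc
        if best is None or inc > increments[best[0].organ_id]:
            best = (t, g, c)
    tree, g, c = best
    agb = wood_agb(c / 10.0, wood_params)  # mm -> cm
    fit = fit_log_linear_rgr(g, np.log(agb))
    return MaxSelection(
        category="trunk",
        member_ids=[tree.organ_id],
        selection_metric=increments,
        trunk_fit=fit,
    )


def fruit_potential_curve(
    thi_fruits: list[OrganTrajectory],
) -> pd.DataFrame:
    """Mean +- SD RGR curve across non-pest-damaged thinned-tree fruits.

    The plain thinned-treatment mean represents the fruit's maximum
    potential growth (no sub-population extraction).
    """
    usable = [f for f in thi_fruits if not f.pest_damaged]
    n_removed = len(thi_fruits) - len(usable)
    if n_removed:
        logger.info("fruit potential: excluded %d pest-damaged fruit(s)", n_removed)
    series = [
        trajectory_rates(f, "dry_mass")
        for f in usable
        if f.values("dry_mass")[0].size >= 2
    ]
    if not series:
        warnings.warn("no usable fruit for the potential-growth curve")
        return pd.DataFrame(columns=["gdd_mid", "mean", "sd", "n"])
    return mean_rate_curve(series)


def fruit_variability_analysis(
    thi_fruits: list[OrganTrajectory],
) -> FruitVariabilityReport:
    """Two OLS diagnostics of fruit variability (pest-damaged excluded).

    Needs >= 3 fruits with both first-date and harvest dry mass and a
    first-interval RGR.
    """
    rows = []
    for f in thi_fruits:
        if f.pest_damaged:
            continue
        g, m = f.values("dry_mass")
        if m.size < 2:
            continue
        rates = trajectory_rates(f, "dry_mass")
        rows.append(
            {
                "initial": m[0],
                "harvest": m[-1],
                "early_rgr": rates.rates[0],
            }
        )
    if len(rows) < 3:
        raise ValueError("need >= 3 usable fruits for the variability analysis")
    df = pd.DataFrame(rows)
    for col in ("initial", "early_rgr"):
        if np.ptp(df[col].to_numpy()) == 0:
            raise ValueError(f"degenerate (constant) predictor {col!r}")
    res_a = stats.linregress(df["initial"], df["harvest"])
    res_b = stats.linregress(df["early_rgr"], df["initial"])
    return FruitVariabilityReport(
        slope_harvest_initial=float(res_a.slope),
        intercept_harvest_initial=float(res_a.intercept),
        r2_harvest_initial=float(res_a.rvalue**2),
        p_harvest_initial=float(res_a.pvalue),
        slope_initial_early_rgr=float(res_b.slope),
        intercept_initial_early_rgr=float(res_b.intercept),
        r2_initial_early_rgr=float(res_b.rvalue**2),
        p_initial_early_rgr=float(res_b.pvalue),
        n_fruits=len(df),
    )
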