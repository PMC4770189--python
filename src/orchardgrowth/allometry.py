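"""Allometric dry-mass estimation for apple tree organs.

Three routes from field-measurable sizes to dry mass:

* fruit volume from three orthogonal diameters (rotational spheroid);
* above-ground woody biomass from trunk circumference via a fixed
  power law ``wood_agb = a * (circumference / pi) ** b`` with published
  coefficients (a = 202.9379 g, b = 1.6115; circumference in cm);
* fitted linear dry-weight models for shoots and fruits on transformed
  predictors (length, log length, log volume, GDD, treatment), selected
  among candidate term sets by AIC.

Model fitting is delegated to statsmodels (OLS for the Gaussian-identity
family, GLM with a Gamma log link as the alternative for right-skewed
masses).  Design matrices are built from a small named-term vocabulary so
that fitted models serialise to plain JSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

TREATMENTS = ("FRU", "DEF", "THI")

#: eq-style shorthand "log(length)*GDD" expanded to main effects + interaction
SHOOT_TERMS = ("length", "log_length", "gdd", "log_length:gdd")
SHOOT_TERMS_PURE_INTERACTION = ("length", "log_length:gdd")
FRUIT_TERMS = ("log_volume", "treatment", "gdd", "treatment:gdd")
FRUIT_TERMS_PURE_INTERACTION = ("log_volume", "treatment:gdd")

DEFAULT_CANDIDATES = {
    "shoot": [
        list(SHOOT_TERMS),
        list(SHOOT_TERMS_PURE_INTERACTION),
        ["length", "gdd"],
        ["length"],
    ],
    "fruit": [
        list(FRUIT_TERMS),
        list(FRUIT_TERMS_PURE_INTERACTION),
        ["log_volume", "gdd"],
        ["log_volume"],
    ],
}


def spheroid_volume(d1, d2, d3):
    """Volume of a rotational spheroid from three orthogonal diameters.

    ``V = 4/3 * pi * r1 * r2 * r3`` with radii ``ri = di / 2``; in the units
    of the inputs cubed (mm diameters -> mm^3).  Symmetric in its arguments.
    """
    d1, d2, d3 = (np.asarray(d, dtype=float) for d in (d1, d2, d3))
    if np.any(d1 <= 0) or np.any(d2 <= 0) or np.any(d3 <= 0):
        raise ValueError("all diameters must be positive")
    out = (math.pi / 6.0) * d1 * d2 * d3
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WoodAllometryParams:
    """Power-law coefficients mapping trunk circumference (cm) to woody
    above-ground biomass (g): ``agb = a * (circumference/pi) ** b``."""

    a: float = 202.9379
    b: float = 1.6115

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometry coefficients must be positive")


def wood_agb(circumference_cm, params: WoodAllometryParams | None = None):
    """Above-ground woody biomass (g) from trunk circumference (cm).

    The circumference is divided by pi, so the base of the power law is the
    trunk diameter; strictly increasing in circumference.
    """
    params = params or WoodAllometryParams()
    c = np.asarray(circumference_cm, dtype=float)
    if np.any(c <= 0):
        raise ValueError("circumference must be positive")
    out = params.a * (c / math.pi) ** params.b
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# design-matrix vocabulary

_NUMERIC_SOURCES = {
    "length": ("length_cm", False),
    "log_length": ("length_cm", True),
    "gdd": ("gdd", False),
    "volume": ("volume_mm3", False),
    "log_volume": ("volume_mm3", True),
}


def _numeric_column(df: pd.DataFrame, name: str) -> np.ndarray:
    col, take_log = _NUMERIC_SOURCES[name]
    if col not in df.columns:
        raise KeyError(f"term {name!r} needs column {col!r}")
    x = df[col].to_numpy(dtype=float)
    if take_log:
        if np.any(x <= 0):
            raise ValueError(f"term {name!r} requires positive {col}")
        x = np.log(x)
    return x


def _treatment_dummies(
    df: pd.DataFrame, levels: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    t = df["treatment"].astype(str)
    unknown = sorted(set(t) - set(levels))
    if unknown:
        raise ValueError(f"unknown treatment level(s): {unknown}")
    cols = [(t == lev).to_numpy(dtype=float) for lev in levels[1:]]
    names = [f"treatment[{lev}]" for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(df), 0)), names


def build_design(
    df: pd.DataFrame,
    terms: list[str],
    treatment_levels: tuple[str, ...] = TREATMENTS,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (intercept first) for the named term list.

    Interaction terms use ``:`` (e.g. ``log_length:gdd``,
    ``treatment:gdd``); ``treatment`` expands to dummy columns against the
    first level of ``treatment_levels`` as reference.
    """
    columns: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for term in terms:
        factors = term.split(":")
        if "treatment" in factors:
            dummies, dnames = _treatment_dummies(df, treatment_levels)
            numeric = [f for f in factors if f != "treatment"]
            block, bnames = dummies, dnames
            for f in numeric:
                x = _numeric_column(df, f)
                block = block * x[:, None]
                bnames = [f"{n}:{f}" for n in bnames]
            for j, n in enumerate(bnames):
                columns.append(block[:, j])
                names.append(n)
        else:
            x = np.ones(len(df))
            for f in factors:
                x = x * _numeric_column(df, f)
            columns.append(x)
            names.append(term)
    return np.column_stack(columns), names


@dataclass
class AllometricModel:
    """A fitted dry-weight model: named terms, coefficients, diagnostics."""

    organ_type: str
    family: str  # "gaussian" | "gamma"
    terms: list[str]
    column_names: list[str]
    coefficients: np.ndarray
    treatment_levels: tuple[str, ...]
    rmse: float
    adj_r2: float
    aic: float
    n_obs: int
    units: dict = field(
        default_factory=lambda: {"length": "cm", "volume": "mm3", "mass": "g"}
    )

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.column_names):
            raise ValueError("one coefficient per design column required")
        if self.rmse < 0:
            raise ValueError("RMSE must be non-negative")

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted dry mass (g) for each row of ``df``.

        ``df`` must carry the raw columns the model's terms need
        (``length_cm``, ``volume_mm3``, ``gdd``, ``treatment``).
        """
        X, names = build_design(df, self.terms, self.treatment_levels)
        if names != self.column_names:
            raise ValueError("design columns do not match fitted model")
        eta = X @ self.coefficients
        out = np.exp(eta) if self.family == "gamma" else eta
        if self.family == "gaussian" and np.any(out <= 0):
            logger.warning(
                "%s model produced %d non-positive mass prediction(s)",
                self.organ_type,
                int(np.sum(out <= 0)),
            )
        return out

    def predict_one(
        self,
        length_cm: float | None = None,
        volume_mm3: float | None = None,
        gdd: float | None = None,
        treatment: str | None = None,
    ) -> float:
        row = {}
        if length_cm is not None:
            row["length_cm"] = length_cm
        if volume_mm3 is not None:
            row["volume_mm3"] = volume_mm3
        if gdd is not None:
            row["gdd"] = gdd
        if treatment is not None:
            row["treatment"] = treatment
        return float(self.predict(pd.DataFrame([row]))[0])

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "organ_type": self.organ_type,
            "family": self.family,
            "terms": list(self.terms),
            "column_names": list(self.column_names),
            "coefficients": self.coefficients.tolist(),
            "treatment_levels": list(self.treatment_levels),
            "rmse": self.rmse,
            "adj_r2": self.adj_r2,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "units": dict(self.units),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AllometricModel":
        d = dict(d)
        d["treatment_levels"] = tuple(d["treatment_levels"])
        d["coefficients"] = np.asarray(d["coefficients"], dtype=float)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "AllometricModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_one(
    y: np.ndarray, X: np.ndarray, names: list[str], family: str
):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns): "
            f"collinear terms among {names}"
        )
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        adj_r2 = float(res.rsquared_adj)
        fitted = np.asarray(res.fittedvalues)
    elif family == "gamma":
        res = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
        fitted = np.asarray(res.fittedvalues)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        dof = len(y) - X.shape[1]
        adj_r2 = float(1.0 - (1.0 - r2) * (len(y) - 1) / dof) if dof > 0 else np.nan
    else:
        raise ValueError(f"unknown family {family!r}")
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return res, rmse, adj_r2


def fit_dry_weight_model(
    records: pd.DataFrame,
    organ_type: str,
    candidate_term_sets: list[list[str]] | None = None,
    family: str = "gaussian",
    treatment_levels: tuple[str, ...] = TREATMENTS,
) -> AllometricModel:
    """Fit each candidate term set by maximum likelihood; keep the AIC
    minimum.

    ``records`` is a calibration table of destructively sampled organs with
    columns ``dry_mass_g``, ``gdd`` and, by organ, ``length_cm`` (shoot) or
    ``volume_mm3`` / diameters ``d1_mm, d2_mm, d3_mm`` (fruit), plus
    ``treatment`` where a treatment term is requested.
    """
    if organ_type not in ("shoot", "fruit"):
        raise ValueError(f"unknown organ_type {organ_type!r}")
    records = records.copy()
    if (
        organ_type == "fruit"
        and "volume_mm3" not in records.columns
        and {"d1_mm", "d2_mm", "d3_mm"} <= set(records.columns)
    ):
        records["volume_mm3"] = spheroid_volume(
            records["d1_mm"], records["d2_mm"], records["d3_mm"]
        )
    if candidate_term_sets is None:
        candidate_term_sets = DEFAULT_CANDIDATES[organ_type]
    if "treatment" in records.columns:
        present = set(records["treatment"].astype(str))
        treatment_levels = tuple(l for l in treatment_levels if l in present)
    y = records["dry_mass_g"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("dry masses must be positive")
    largest = max(len(t) for t in candidate_term_sets)
    if len(records) < largest + 1 + 5:
        raise ValueError(
            f"need at least {largest + 6} records for {largest}-term candidates, "
            f"got {len(records)}"
        )

    best = None
    for terms in candidate_term_sets:
        X, names = build_design(records, terms, treatment_levels)
        res, rmse, adj_r2 = _fit_one(y, X, names, family)
        aic = float(res.aic)
        logger.info(
            "%s %s candidate %s: AIC=%.2f RMSE=%.3f", organ_type, family, terms, aic, rmse
        )
        if best is None or aic < best[0]:
            best = (aic, terms, names, np.asarray(res.params), rmse, adj_r2)
    aic, terms, names, coefs, rmse, adj_r2 = best
    return AllometricModel(
        organ_type=organ_type,
        family=family,
        terms=list(terms),
        column_names=list(names),
        coefficients=coefs,
        treatment_levels=treatment_levels,
        rmse=rmse,
        adj_r2=adj_r2,
        aic=aic,
        n_obs=len(records),
    )


def predict_dry_weight(
    model: AllometricModel,
    length_cm: float | None = None,
    volume_mm3: float | None = None,
    gdd: float | None = None,
    treatment: str | None = None,
) -> float:
    """Convenience scalar wrapper around :meth:`AllometricModel.predict`."""
    return model.predict_one(
        length_cm=length_cm, volume_mm3=volume_mm3, gdd=gdd, treatment=treatment
    )
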