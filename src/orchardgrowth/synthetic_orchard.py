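"""Synthetic orchard: weather and measurement tables with known truth.

Emulates a season of field data from a three-treatment apple experiment —
defruited (DEF), heavily thinned (THI) and unmanipulated control (FRU)
trees, five per treatment — with the statistical structure the analysis
pipeline assumes:

* hourly weather as seasonal trend + diurnal sinusoid + noise;
* shoot length logistic in GDD, with class-specific cessation (proleptic
  shoots finish early, epicormic shoots grow into late summer, control
  shoots stay shorter than defruited ones) and a spur fraction;
* shoot dry mass from a known linear length/GDD rule, so calibration-model
  fitting has a recoverable truth;
* fruit dry mass expolinear in GDD (exponential then linear), with
  per-fruit set-time jitter that induces the negative correlation between
  initial mass and early-season RGR seen in thinned-tree fruit;
* trunk woody biomass exponential in GDD with treatment-specific RGR.

Generating parameters are stored per organ and retrievable via
:func:`ground_truth` for recovery tests.  All randomness flows from one
root seed through named substreams.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .allometry import WoodAllometryParams
from .thermal_time import ThermalTimeAxis, accumulate_gdd

CANOPY_LEVELS = ("low", "medium", "high")


@dataclass
class OrchardConfig:
    """Study conditions of the emulated experiment.

    Defaults mirror the field design: 15 trees in three groups of five;
    thinned trees keep at most one fruit per bourse shoot or spur (nine
    tagged fruits/tree), control trees carry 0.47 fruits per shoot; shoots
    measured biweekly April-July and monthly thereafter; trunk collars read
    from about seven weeks after bloom at 1 mm precision.
    """

    n_trees_per_treatment: int = 5
    shoots_per_tree: int = 12
    thi_fruits_per_tree: int = 9
    fru_fruits_per_shoot: float = 0.47
    epicormic_fraction: float = 0.2  # among defruited-tree shoots
    spur_fraction: float = 0.15
    bloom_date: str = "2014-04-02"
    season_days: int = 190
    # weather model (degC)
    weather_mean: float = 10.5
    weather_seasonal_amplitude: float = 8.0
    weather_diurnal_amplitude: float = 6.0
    weather_noise_sd: float = 1.5
    # shoot growth (length cm; GDD in degC day)
    shoot_asymptote_fru: float = 22.0
    shoot_asymptote_def: float = 28.0  # control shoots end ~28% shorter
    shoot_asymptote_epicormic: float = 96.0
    shoot_asymptote_spur: float = 2.5
    shoot_asymptote_cv: float = 0.15
    shoot_rate_fru: float = 0.012
    shoot_rate_def: float = 0.010
    shoot_rate_epicormic: float = 0.003
    shoot_midpoint_fru: float = 230.0
    shoot_midpoint_def: float = 280.0
    shoot_midpoint_epicormic: float = 1200.0
    # known length->mass rule: m0 + m_len*L + m_int*log(L)*gdd  (g)
    shoot_mass_rule: dict = field(
        default_factory=lambda: {"m0": 0.1, "m_len": 0.08, "m_int": 0.0004}
    )
    # fruit expolinear growth (dry mass g)
    fruit_linear_rate_thi: float = 0.022  # g per GDD in the linear phase
    fruit_linear_rate_fru: float = 0.015
    fruit_max_rgr_thi: float = 0.009  # per GDD, early exponential phase
    fruit_max_rgr_fru: float = 0.0065
    fruit_transition_gdd: float = 450.0
    fruit_set_jitter_sd_gdd: float = 60.0
    fruit_rate_cv: float = 0.12
    fruit_rgr_cv: float = 0.05
    pest_damage_rate: float = 0.08
    late_season_decline: bool = False
    late_decline_fraction: float = 0.06
    late_decline_onset_gdd: float = 1750.0
    # fruit dry-matter density rises through the season (g per mm^3)
    fruit_density_intercept: float = 8e-5
    fruit_density_slope: float = 3e-8
    fruit_shape_jitter_sd: float = 0.03  # log-sd of diameter anisotropy
    # trunk growth
    trunk_rgr_fru: float = 2.5e-5  # per GDD on ln(wood AGB)
    trunk_rgr_def: float = 9.0e-5
    trunk_rgr_thi: float = 5.0e-5
    trunk_rgr_cv: float = 0.3  # Max tree runs ~50% above the group mean
    trunk_circumference0_mm: float = 240.0
    trunk_circumference0_sd_mm: float = 15.0
    trunk_start_day: int = 49  # collars installed ~7 weeks after bloom
    # measurement noise (coefficients of variation, multiplicative)
    length_cv: float = 0.03
    diameter_cv: float = 0.02
    circumference_cv: float = 0.0015  # 1 mm collar precision on ~240 mm
    calibration_mass_cv: float = 0.05
    # calibration sampling
    calibration_shoots_per_date: int = 30
    calibration_fruits_per_date: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_trees_per_treatment",
            "shoots_per_tree",
            "thi_fruits_per_tree",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("epicormic_fraction", "spur_fraction", "pest_damage_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("length_cv", "diameter_cv", "circumference_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# -- latent trajectories ----------------------------------------------------


@dataclass
class ShootParams:
    shoot_id: str
    tree_id: str
    treatment: str
    shoot_class: str  # proleptic | epicormic
    is_spur: bool
    canopy_level: str
    pruning_trace: bool
    asymptote_cm: float
    rate: float
    midpoint_gdd: float


@dataclass
class FruitParams:
    fruit_id: str
    tree_id: str
    treatment: str
    linear_rate: float
    max_rgr: float
    transition_gdd: float  # includes the per-fruit set-time offset
    set_offset_gdd: float
    pest_damaged: bool


@dataclass
class TreeParams:
    tree_id: str
    treatment: str
    trunk_rgr: float
    agb0_g: float


def latent_shoot_length(p: ShootParams, gdd) -> np.ndarray:
    """Logistic elongation: ``A / (1 + exp(-r (g - gm)))`` (cm)."""
    g = np.asarray(gdd, dtype=float)
    return p.asymptote_cm / (1.0 + np.exp(-p.rate * (g - p.midpoint_gdd)))


def shoot_mass_from_length(length_cm, gdd, rule: dict) -> np.ndarray:
    """The generator's known length->dry-mass rule (floored at 0.02 g)."""
    L = np.asarray(length_cm, dtype=float)
    g = np.asarray(gdd, dtype=float)
    m = rule["m0"] + rule["m_len"] * L + rule["m_int"] * np.log(L) * g
    return np.maximum(m, 0.02)


def latent_fruit_mass(p: FruitParams, gdd, config: OrchardConfig | None = None):
    """Expolinear fruit dry mass: exponential phase turning linear.

    ``W(g) = (c/r) ln(1 + exp(r (g - tb)))`` with linear-phase rate ``c``,
    maximum RGR ``r`` and transition ``tb``; an optional late-season decline
    multiplies in a shallow downward ramp after its onset.
    """
    g = np.asarray(gdd, dtype=float)
    w = (p.linear_rate / p.max_rgr) * np.logaddexp(
        0.0, p.max_rgr * (g - p.transition_gdd)
    )
    if config is not None and config.late_season_decline:
        ramp = np.clip((g - config.late_decline_onset_gdd) / 200.0, 0.0, 1.0)
        w = w * (1.0 - config.late_decline_fraction * ramp)
    return w


def fruit_volume_from_mass(mass_g, gdd, config: OrchardConfig) -> np.ndarray:
    """Invert the seasonal dry-matter density to get fruit volume (mm^3)."""
    g = np.asarray(gdd, dtype=float)
    rho = config.fruit_density_intercept + config.fruit_density_slope * g
    return np.asarray(mass_g, dtype=float) / rho


def latent_trunk_agb(p: TreeParams, gdd) -> np.ndarray:
    """Woody above-ground biomass (g), exponential in GDD."""
    g = np.asarray(gdd, dtype=float)
    return p.agb0_g * np.exp(p.trunk_rgr * g)


def trunk_circumference_mm(
    p: TreeParams, gdd, wood_params: WoodAllometryParams | None = None
) -> np.ndarray:
    """Circumference (mm) consistent with the wood allometry in cm/g."""
    wp = wood_params or WoodAllometryParams()
    agb = latent_trunk_agb(p, gdd)
    return 10.0 * math.pi * (agb / wp.a) ** (1.0 / wp.b)


# -- generation -------------------------------------------------------------


@dataclass
class Orchard:
    config: OrchardConfig
    weather: pd.Series
    axis: ThermalTimeAxis
    trees: list[TreeParams]
    shoots: list[ShootParams]
    fruits: list[FruitParams]


def generate_weather(config: OrchardConfig, seed: int | None = None) -> pd.Series:
    """Hourly temperatures: seasonal trend + diurnal sinusoid + noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    start = pd.Timestamp(config.bloom_date) - pd.Timedelta(days=1)
    idx = pd.date_range(start, periods=(config.season_days + 2) * 24, freq="1h")
    day = (idx - idx[0]).total_seconds().to_numpy() / 86400.0
    hour = idx.hour.to_numpy()
    seasonal = config.weather_mean + config.weather_seasonal_amplitude * np.sin(
        math.pi * day / (config.season_days + 10)
    )
    diurnal = config.weather_diurnal_amplitude * np.cos(
        2.0 * math.pi * (hour - 15) / 24.0
    )
    noise = (
        rng.normal(0.0, config.weather_noise_sd, len(idx))
        if config.weather_noise_sd > 0
        else 0.0
    )
    return pd.Series(seasonal + diurnal + noise, index=idx, name="temp_c")


def _make_tree(config, treatment, tree_id, rng) -> TreeParams:
    base = {
        "FRU": config.trunk_rgr_fru,
        "DEF": config.trunk_rgr_def,
        "THI": config.trunk_rgr_thi,
    }[treatment]
    rgr = base * rng.lognormal(0.0, config.trunk_rgr_cv)
    c0 = max(
        rng.normal(config.trunk_circumference0_mm, config.trunk_circumference0_sd_mm),
        50.0,
    )
    wp = WoodAllometryParams()
    agb0 = wp.a * (c0 / 10.0 / math.pi) ** wp.b
    return TreeParams(tree_id=tree_id, treatment=treatment, trunk_rgr=rgr, agb0_g=agb0)


def _make_shoot(config, treatment, tree_id, idx, rng) -> ShootParams:
    is_spur = rng.random() < config.spur_fraction
    if treatment == "DEF" and not is_spur:
        epicormic = rng.random() < config.epicormic_fraction
    else:
        epicormic = False
    if is_spur:
        a, r, gm = config.shoot_asymptote_spur, 0.015, 150.0
        cls = "proleptic"
    elif epicormic:
        a = config.shoot_asymptote_epicormic
        r, gm = config.shoot_rate_epicormic, config.shoot_midpoint_epicormic
        cls = "epicormic"
    elif treatment == "DEF":
        a = config.shoot_asymptote_def
        r, gm = config.shoot_rate_def, config.shoot_midpoint_def
        cls = "proleptic"
    else:
        a = config.shoot_asymptote_fru
        r, gm = config.shoot_rate_fru, config.shoot_midpoint_fru
        cls = "proleptic"
    a = a * rng.lognormal(0.0, config.shoot_asymptote_cv)
    return ShootParams(
        shoot_id=f"{tree_id}_S{idx:02d}",
        tree_id=tree_id,
        treatment=treatment,
        shoot_class=cls,
        is_spur=is_spur,
        canopy_level=CANOPY_LEVELS[rng.integers(0, 3)],
        pruning_trace=epicormic,
        asymptote_cm=a,
        rate=r,
        midpoint_gdd=gm,
    )


def _make_fruit(config, treatment, tree_id, idx, rng) -> FruitParams:
    if treatment == "THI":
        c, r = config.fruit_linear_rate_thi, config.fruit_max_rgr_thi
    else:
        c, r = config.fruit_linear_rate_fru, config.fruit_max_rgr_fru
    c = c * rng.lognormal(0.0, config.fruit_rate_cv)
    r = r * rng.lognormal(0.0, config.fruit_rgr_cv)
    offset = rng.normal(0.0, config.fruit_set_jitter_sd_gdd)
    return FruitParams(
        fruit_id=f"{tree_id}_F{idx:02d}",
        tree_id=tree_id,
        treatment=treatment,
        linear_rate=c,
        max_rgr=r,
        transition_gdd=config.fruit_transition_gdd + offset,
        set_offset_gdd=offset,
        pest_damaged=rng.random() < config.pest_damage_rate,
    )


def generate_orchard(config: OrchardConfig | None = None, seed: int | None = None) -> Orchard:
    """Generate weather, thermal axis and latent organ parameters.

    Reproducible: the root seed (argument, else ``config.seed``) spawns
    independent substreams for weather and for each treatment's trees.
    """
    config = config or OrchardConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    weather_ss, tree_ss = root.spawn(2)
    weather = generate_weather(config, seed=weather_ss.generate_state(1)[0] % 2**31)
    axis = accumulate_gdd(weather, config.bloom_date)
    rng = np.random.default_rng(tree_ss)
    trees, shoots, fruits = [], [], []
    for treatment in ("FRU", "DEF", "THI"):
        for t in range(config.n_trees_per_treatment):
            tree_id = f"{treatment}{t + 1}"
            tree = _make_tree(config, treatment, tree_id, rng)
            trees.append(tree)
            if treatment in ("FRU", "DEF"):
                for s in range(config.shoots_per_tree):
                    shoots.append(_make_shoot(config, treatment, tree_id, s, rng))
            if treatment == "THI":
                n_fruit = config.thi_fruits_per_tree
            elif treatment == "FRU":
                n_fruit = rng.binomial(config.shoots_per_tree, config.fru_fruits_per_shoot)
            else:
                n_fruit = 0
            for f in range(n_fruit):
                fruits.append(_make_fruit(config, treatment, tree_id, f, rng))
    return Orchard(
        config=config, weather=weather, axis=axis, trees=trees, shoots=shoots, fruits=fruits
    )


def measurement_schedule(config: OrchardConfig) -> list[pd.Timestamp]:
    """Biweekly dates April-July, monthly thereafter, ending near harvest."""
    bloom = pd.Timestamp(config.bloom_date)
    dates = [bloom + pd.Timedelta(days=14 * k) for k in range(1, 9)]
    d = dates[-1] + pd.Timedelta(days=28)
    last = bloom + pd.Timedelta(days=config.season_days - 3)
    while d < last:
        dates.append(d)
        d += pd.Timedelta(days=28)
    dates.append(last)
    return dates


def _jittered_diameters(volume_mm3, rng, shape_sd: float):
    """Three orthogonal diameters whose spheroid volume is exactly the
    latent volume (anisotropy jitter preserves the product)."""
    d_eq = (6.0 * np.asarray(volume_mm3, dtype=float) / math.pi) ** (1.0 / 3.0)
    j1 = rng.lognormal(0.0, shape_sd, d_eq.shape)
    j2 = rng.lognormal(0.0, shape_sd, d_eq.shape)
    return d_eq * j1, d_eq * j2, d_eq / (j1 * j2)


def sample_measurements(
    orchard: Orchard,
    seed: int | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Sample the latent orchard on the measurement schedule.

    Emits one long-format row per organ and date in the measurement-table
    schema (sizes only; dry mass is what the analysis has to estimate).
    Measurement noise is multiplicative log-normal at the configured CVs;
    ``noise=False`` returns the latent values exactly.
    """
    config = orchard.config
    rng = np.random.default_rng(
        (orchard.config.seed + 7919) % 2**31 if seed is None else seed
    )
    dates = measurement_schedule(config)
    bloom = pd.Timestamp(config.bloom_date)
    gdds = np.array([orchard.axis.gdd_at(d) for d in dates])
    rows = []

    def mult(cv, n):
        return rng.lognormal(0.0, cv, n) if (noise and cv > 0) else np.ones(n)

    for shoot in orchard.shoots:
        lengths = latent_shoot_length(shoot, gdds) * mult(config.length_cv, len(gdds))
        for d, g, L in zip(dates, gdds, lengths):
            rows.append(
                {
                    "organ_id": shoot.shoot_id,
                    "tree_id": shoot.tree_id,
                    "treatment": shoot.treatment,
                    "organ_type": "shoot",
                    "canopy_level": shoot.canopy_level,
                    "pruning_trace": shoot.pruning_trace,
                    "pest_damaged": False,
                    "date": d.strftime("%Y-%m-%d"),
                    "length_cm": L,
                }
            )
    for fruit in orchard.fruits:
        masses = latent_fruit_mass(fruit, gdds, config)
        volumes = fruit_volume_from_mass(masses, gdds, config)
        d1, d2, d3 = _jittered_diameters(
            volumes, rng, config.fruit_shape_jitter_sd if noise else 0.0
        )
        d1 = d1 * mult(config.diameter_cv, len(gdds))
        d2 = d2 * mult(config.diameter_cv, len(gdds))
        d3 = d3 * mult(config.diameter_cv, len(gdds))
        for d, g, a, b, c in zip(dates, gdds, d1, d2, d3):
            rows.append(
                {
                    "organ_id": fruit.fruit_id,
                    "tree_id": fruit.tree_id,
                    "treatment": fruit.treatment,
                    "organ_type": "fruit",
                    "pest_damaged": fruit.pest_damaged,
                    "pruning_trace": False,
                    "date": d.strftime("%Y-%m-%d"),
                    "d1_mm": a,
                    "d2_mm": b,
                    "d3_mm": c,
                }
            )
    trunk_dates = [
        (d, g)
        for d, g in zip(dates, gdds)
        if (d - bloom).days >= config.trunk_start_day
    ]
    for tree in orchard.trees:
        if tree.treatment == "THI":
            continue  # collars installed on control and defruited trees
        gs = np.array([g for _, g in trunk_dates])
        circ = trunk_circumference_mm(tree, gs) * mult(
            config.circumference_cv, len(gs)
        )
        for (d, g), c in zip(trunk_dates, circ):
            rows.append(
                {
                    "organ_id": f"{tree.tree_id}_T",
                    "tree_id": tree.tree_id,
                    "treatment": tree.treatment,
                    "organ_type": "trunk",
                    "pest_damaged": False,
                    "pruning_trace": False,
                    "date": d.strftime("%Y-%m-%d"),
                    "circumference_mm": c,
                }
            )
    return pd.DataFrame(rows)


def generate_calibration(
    orchard: Orchard, seed: int | None = None, noise: bool = True
) -> pd.DataFrame:
    """Destructive calibration samples: sizes plus oven-dry mass.

    Shoots are drawn from the control-tree population (the dry-weight model
    is built on control samples), fruits from both control and thinned
    trees, on alternating schedule dates.
    """
    config = orchard.config
    rng = np.random.default_rng(
        (config.seed + 104729) % 2**31 if seed is None else seed
    )
    dates = measurement_schedule(config)
    gdds = np.array([orchard.axis.gdd_at(d) for d in dates])
    rows = []

    def mult(cv):
        return rng.lognormal(0.0, cv) if (noise and cv > 0) else 1.0

    shoot_dates = list(zip(dates, gdds))[::2]
    for d, g in shoot_dates:
        for i in range(config.calibration_shoots_per_date):
            proto = _make_shoot(config, "FRU", "CAL", i, rng)
            if proto.is_spur:
                continue
            L = float(latent_shoot_length(proto, g)) * mult(config.length_cv)
            if L < 1.0:
                continue
            mass = float(shoot_mass_from_length(L, g, config.shoot_mass_rule)) * mult(
                config.calibration_mass_cv
            )
            rows.append(
                {
                    "organ_type": "shoot",
                    "tree_id": "CAL",
                    "treatment": "FRU",
                    "date": d.strftime("%Y-%m-%d"),
                    "length_cm": L,
                    "dry_mass_g": mass,
                }
            )
    fruit_dates = list(zip(dates, gdds))[1::2]
    for d, g in fruit_dates:
        for treatment in ("FRU", "THI"):
            for i in range(config.calibration_fruits_per_date):
                proto = _make_fruit(config, treatment, "CAL", i, rng)
                mass = float(latent_fruit_mass(proto, g, config))
                vol = float(fruit_volume_from_mass(mass, g, config))
                d1, d2, d3 = _jittered_diameters(
                    np.array([vol]), rng, config.fruit_shape_jitter_sd if noise else 0.0
                )
                rows.append(
                    {
                        "organ_type": "fruit",
                        "tree_id": "CAL",
                        "treatment": treatment,
                        "date": d.strftime("%Y-%m-%d"),
                        "d1_mm": float(d1[0]) * mult(config.diameter_cv),
                        "d2_mm": float(d2[0]) * mult(config.diameter_cv),
                        "d3_mm": float(d3[0]) * mult(config.diameter_cv),
                        "dry_mass_g": mass * mult(config.calibration_mass_cv),
                    }
                )
    return pd.DataFrame(rows)


# -- ground truth -----------------------------------------------------------


@dataclass
class GroundTruth:
    """Complete generating-parameter record for recovery tests."""

    shoot_mass_rule: dict
    shoots: list[ShootParams]
    fruits: list[FruitParams]
    trees: list[TreeParams]
    trunk_rgr_by_treatment: dict  # treatment -> mean of realized per-tree RGRs

    def max_trunk_tree(self, treatment: str = "DEF") -> str:
        trees = [t for t in self.trees if t.treatment == treatment]
        return max(trees, key=lambda t: t.trunk_rgr).tree_id

    def to_dict(self) -> dict:
        return {
            "shoot_mass_rule": dict(self.shoot_mass_rule),
            "shoots": [asdict(s) for s in self.shoots],
            "fruits": [asdict(f) for f in self.fruits],
            "trees": [asdict(t) for t in self.trees],
            "trunk_rgr_by_treatment": dict(self.trunk_rgr_by_treatment),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            shoot_mass_rule=d["shoot_mass_rule"],
            shoots=[ShootParams(**s) for s in d["shoots"]],
            fruits=[FruitParams(**f) for f in d["fruits"]],
            trees=[TreeParams(**t) for t in d["trees"]],
            trunk_rgr_by_treatment=d["trunk_rgr_by_treatment"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def ground_truth(orchard: Orchard) -> GroundTruth:
    """Generating parameters of an orchard (independent of any sampling)."""
    by_treatment = {}
    for treatment in ("FRU", "DEF", "THI"):
        rgrs = [t.trunk_rgr for t in orchard.trees if t.treatment == treatment]
        if rgrs:
            by_treatment[treatment] = float(np.mean(rgrs))
    return GroundTruth(
        shoot_mass_rule=dict(orchard.config.shoot_mass_rule),
        shoots=list(orchard.shoots),
        fruits=list(orchard.fruits),
        trees=list(orchard.trees),
        trunk_rgr_by_treatment=by_treatment,
    )
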