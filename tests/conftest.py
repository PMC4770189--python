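"""Shared fixtures: a seeded synthetic orchard and its report bundle."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import orchardgrowth as og
from orchardgrowth.cli_io import run_report


@pytest.fixture(scope="session")
def orchard():
    return og.generate_orchard(og.OrchardConfig(seed=0))


@pytest.fixture(scope="session")
def orchard_tables(orchard):
    return og.sample_measurements(orchard), og.generate_calibration(orchard)


@pytest.fixture(scope="session")
def report_bundle(orchard, orchard_tables):
    measurements, calibration = orchard_tables
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_report(
            measurements,
            orchard.weather,
            calibration,
            orchard.config.bloom_date,
        )


def make_trajectory(
    organ_id="org",
    organ_type="shoot",
    treatment="DEF",
    gdd=(0.0, 100.0, 200.0),
    **columns,
):
    """Small helper to build an OrganTrajectory from keyword columns."""
    obs = pd.DataFrame({"gdd": np.asarray(gdd, dtype=float), **columns})
    extra = {}
    for key in ("pruning_trace", "pest_damaged", "shoot_class"):
        if key in columns:
            extra[key] = columns.pop(key)
    return og.OrganTrajectory(
        organ_id=organ_id,
        tree_id="T1",
        treatment=treatment,
        organ_type=organ_type,
        observations=obs,
        **extra,
    )


@pytest.fixture
def trajectory_factory():
    return make_trajectory


def constant_day(temp: float, date="2014-05-01") -> pd.Series:
    idx = pd.date_range(date, periods=24, freq="1h")
    return pd.Series(np.full(24, float(temp)), index=idx)


@pytest.fixture
def constant_day_factory():
    return constant_day
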