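"""Shared fixtures: generated regions and campaigns at several scales.

Everything is generated programmatically with fixed seeds; the full-scale
rural campaign (~24.5k biweekly measurements) is built once per session and
shared by the statistical tests.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from stlur.regression import fit_terms
from stlur.synthetic import (
    generate_measurements,
    generate_region,
    rural_config,
    urban_config,
)
from stlur.terms import parse_term


@pytest.fixture(scope="session")
def small_region():
    """A compact rural region (20 sites, 2 years) for fast pipeline tests."""
    cfg = rural_config(n_sites=20, campaign_end=dt.date(1999, 12, 31), seed=42)
    return generate_region(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_region):
    meas, pred = generate_measurements(small_region)
    return small_region, meas, pred


@pytest.fixture(scope="session")
def rural_dataset():
    """The default full-scale rural campaign: ~24.5k measurements."""
    cfg = rural_config(seed=11)
    region = generate_region(cfg)
    meas, pred = generate_measurements(region)
    return region, cfg, meas, pred


@pytest.fixture(scope="session")
def rural_full_predictors(rural_dataset):
    """Predictor table for every site-period of the rural campaign (before
    the completeness draw), for cheap replicate redraws."""
    from stlur.pipeline import build_predictor_table
    from stlur.synthetic import campaign_periods

    region, cfg, _, _ = rural_dataset
    periods = campaign_periods(cfg)
    shell = pd.DataFrame(
        [
            {"site_id": s, "period_start": p0, "period_end": p1}
            for s in region.sites.site_id
            for (p0, p1) in periods
        ]
    )
    return build_predictor_table(region, shell)


@pytest.fixture(scope="session")
def rural_truth_terms(rural_dataset):
    _, cfg, _, _ = rural_dataset
    return [parse_term(k) for k in cfg.truth_coefficients]


@pytest.fixture(scope="session")
def rural_fit(rural_dataset, rural_truth_terms):
    _, _, meas, pred = rural_dataset
    y = np.log(meas.no2.to_numpy(float))
    return fit_terms(rural_truth_terms, pred, y)


@pytest.fixture(scope="session")
def urban_dataset():
    cfg = urban_config(seed=13)
    region = generate_region(cfg)
    meas, pred = generate_measurements(region)
    return region, cfg, meas, pred
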