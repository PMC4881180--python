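"""Coefficient-table engine: parsing, prediction, per-IQR effects, windows."""

import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest

from stlur.exposure import (
    ExposureWindow,
    load_bern_table,
    parse_coefficient_table,
    per_iqr_effect,
    predict_no2,
    pregnancy_windows,
    window_exposure,
)


@pytest.fixture(scope="module")
def rural_table():
    return load_bern_table("rural")


@pytest.fixture(scope="module")
def urban_table():
    return load_bern_table("urban")


def test_parse_recovers_raw_beta_from_iqr_row(rural_table):
    row = rural_table.row("log(aqm_no2)")
    assert row.beta == pytest.approx(0.250 / (2.98 - 2.28), rel=1e-12)


def test_parse_land_use_row_beta_is_estimate(rural_table):
    assert rural_table.row("lu_highdens_200").beta == pytest.approx(0.410)


def test_parse_errors_name_the_problem():
    base = (
        "region_kind,variable,label,p25,p50,p75,estimate,ci_low,ci_high,"
        "cum_adj_r2,scaling,percentiles_ambiguous\n"
    )
    with pytest.raises(ValueError, match="IQR"):
        parse_coefficient_table(
            pd.read_csv(io.StringIO(base + "rural,x,X,1,1,1,0.5,0.4,0.6,0.1,iqr,False\n"))
        )
    with pytest.raises(ValueError, match="scaling"):
        parse_coefficient_table(
            pd.read_csv(io.StringIO(base + "rural,x,X,0,1,2,0.5,0.4,0.6,0.1,wat,False\n"))
        )
    with pytest.raises(ValueError, match="missing columns"):
        parse_coefficient_table(pd.DataFrame({"variable": ["x"]}))


def test_predict_all_zero_inputs_is_the_no_intercept_point(rural_table):
    vals = {a.strip() for v in rural_table.variables for a in v.split("*")}
    log_pred, conc = predict_no2(rural_table, {a: 0.0 for a in vals})
    assert log_pred == 0.0
    assert conc == 1.0


def test_predict_is_linear_on_log_scale(rural_table):
    atoms = {a.strip() for v in rural_table.variables for a in v.split("*")}
    rng = np.random.default_rng(0)
    va = {a: float(rng.uniform(0, 2)) for a in atoms}
    vb = {a: float(rng.uniform(0, 2)) for a in atoms}
    interactions = [v for v in rural_table.variables if "*" in v]
    # linearity holds exactly when interaction inputs are additive too; hold
    # one partner fixed at zero to stay in the linear regime
    for v in interactions:
        p = v.split("*")[1].strip()
        va[p] = vb[p] = 0.0
    la, _ = predict_no2(rural_table, va)
    lb, _ = predict_no2(rural_table, vb)
    lab, _ = predict_no2(rural_table, {a: va[a] + vb[a] for a in va})
    assert lab == pytest.approx(la + lb, rel=1e-10)


def test_predict_missing_variable_lists_names(rural_table):
    with pytest.raises(ValueError, match="season"):
        predict_no2(rural_table, {"log(aqm_no2)": 2.5})


def test_predict_period_supplies_season_and_trend(rural_table):
    atoms = {a.strip() for v in rural_table.variables for a in v.split("*")}
    vals = {a: 0.0 for a in atoms if a not in ("season", "year", "square(year)")}
    period = (dt.date(2004, 7, 1), dt.date(2004, 7, 15))
    log_pred, _ = predict_no2(rural_table, vals, period=period)
    expected = (
        rural_table.row("season").beta * 1
        + rural_table.row("year").beta * 2004.52
        + rural_table.row("square(year)").beta * 2004.52**2
    )
    assert log_pred == pytest.approx(expected, rel=1e-3)


def test_per_iqr_effect_matches_printed_estimates(rural_table, urban_table):
    assert per_iqr_effect(rural_table, "temperature") == pytest.approx(-0.102)
    assert per_iqr_effect(rural_table, "log(aqm_no2)") == pytest.approx(0.250)
    assert per_iqr_effect(urban_table, "log(aqm_no2)") == pytest.approx(0.216)
    assert per_iqr_effect(rural_table, "lu_highdens_200") == pytest.approx(0.410)
    with pytest.raises(KeyError):
        per_iqr_effect(rural_table, "nope")


def test_window_exposure_arithmetic():
    w = ExposureWindow("custom", dt.date(2004, 1, 1), dt.date(2004, 1, 29))
    const = pd.DataFrame(
        {
            "period_start": [dt.date(2004, 1, 1), dt.date(2004, 1, 15)],
            "period_end": [dt.date(2004, 1, 15), dt.date(2004, 1, 29)],
            "no2": [20.0, 20.0],
        }
    )
    assert window_exposure(const, w) == pytest.approx(20.0)
    two = const.assign(no2=[10.0, 30.0])
    assert window_exposure(two, w) == pytest.approx(20.0)
    inner = ExposureWindow("custom", dt.date(2004, 1, 3), dt.date(2004, 1, 10))
    assert window_exposure(two, inner) == pytest.approx(10.0)


def test_window_exposure_invariant_to_period_splitting():
    w = ExposureWindow("custom", dt.date(2004, 3, 1), dt.date(2004, 3, 29))
    whole = pd.DataFrame(
        {
            "period_start": [dt.date(2004, 3, 1)],
            "period_end": [dt.date(2004, 3, 29)],
            "no2": [17.3],
        }
    )
    split = pd.DataFrame(
        {
            "period_start": [dt.date(2004, 3, 1), dt.date(2004, 3, 8),
                             dt.date(2004, 3, 15)],
            "period_end": [dt.date(2004, 3, 8), dt.date(2004, 3, 15),
                           dt.date(2004, 3, 29)],
            "no2": [17.3, 17.3, 17.3],
        }
    )
    assert window_exposure(whole, w) == pytest.approx(window_exposure(split, w))


def test_window_exposure_coverage_guard():
    w = ExposureWindow("custom", dt.date(2004, 1, 1), dt.date(2004, 3, 1))
    sparse = pd.DataFrame(
        {
            "period_start": [dt.date(2004, 1, 1)],
            "period_end": [dt.date(2004, 1, 15)],
            "no2": [20.0],
        }
    )
    with pytest.raises(ValueError, match="covered"):
        window_exposure(sparse, w)


def test_pregnancy_windows_trimester_boundaries():
    conception = dt.date(2004, 1, 1)
    delivery = conception + dt.timedelta(weeks=40)
    windows = {w.kind: w for w in pregnancy_windows(conception, delivery)}
    assert windows["trimester1"].start == conception
    assert windows["trimester1"].end == conception + dt.timedelta(weeks=13)
    assert windows["trimester2"].end == conception + dt.timedelta(weeks=27)
    assert windows["trimester3"].end == delivery
    assert windows["full_pregnancy"].days == 280
    assert windows["first_year"].days == 365
    with pytest.raises(ValueError):
        pregnancy_windows(delivery, conception)
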