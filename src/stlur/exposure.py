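"""Exposure prediction from published-style coefficient tables.

The final rural/urban models are distributed as per-IQR coefficient tables
(variable, 25/50/75 percentiles on the scale the term enters the model,
estimate per IQR with 95 % CI, cumulative adjusted R^2).  This module parses
that dialect back to raw log-scale coefficients, predicts NO2 for arbitrary
predictor values, reproduces per-IQR effects, and aggregates period
predictions over pregnancy-relevant exposure windows.

CSV dialect (one row per model term)::

    region_kind, variable, label, p25, p50, p75, estimate, ci_low, ci_high,
    cum_adj_r2, scaling, percentiles_ambiguous

``variable`` is the canonical term string (``log(aqm_no2)``,
``square(year)``, ``road_major_len_100 * season``); inputs to transformed
terms are supplied on the transformed scale exactly as labelled.  ``scaling``
is ``iqr`` (estimate = beta * (p75 - p25)) or ``per_0_to_100`` (land-use
fractions coded 0-1; estimate = beta directly).  Rows whose printed
percentiles could not be read unambiguously are flagged
``percentiles_ambiguous`` and excluded from round-trip checks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CoefficientTable",
    "ExposureWindow",
    "parse_coefficient_table",
    "load_bern_table",
    "predict_no2",
    "per_iqr_effect",
    "window_exposure",
    "pregnancy_windows",
]

_COLUMNS = [
    "region_kind", "variable", "label", "p25", "p50", "p75",
    "estimate", "ci_low", "ci_high", "cum_adj_r2", "scaling",
    "percentiles_ambiguous",
]


@dataclass
class CoefficientTable:
    """A parsed coefficient table with recovered raw betas."""

    rows: pd.DataFrame  # dialect columns + beta
    region_kind: str

    @property
    def variables(self) -> list[str]:
        return self.rows.variable.tolist()

    def row(self, variable: str) -> pd.Series:
        hit = self.rows[self.rows.variable == variable]
        if hit.empty:
            raise KeyError(
                f"unknown variable {variable!r}; known: {self.variables}"
            )
        return hit.iloc[0]


def _atoms(variable: str) -> list[str]:
    return [a.strip() for a in variable.split("*")]


def parse_coefficient_table(source: Path | str | pd.DataFrame) -> CoefficientTable:
    """Parse the coefficient-table CSV dialect and recover raw betas.

    ``beta = estimate / (p75 - p25)`` for IQR-scaled rows (a zero IQR on such
    a row is a parse error) and ``beta = estimate`` for the 0 -> 100 %
    land-use rows.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coefficient table missing columns {sorted(missing)}")
    betas = []
    for i, row in df.iterrows():
        if row.scaling == "per_0_to_100":
            betas.append(float(row.estimate))
        elif row.scaling == "iqr":
            iqr = float(row.p75) - float(row.p25)
            if iqr <= 0:
                raise ValueError(
                    f"row {i} ({row.variable}): IQR-scaled row with IQR {iqr}"
                )
            betas.append(float(row.estimate) / iqr)
        else:
            raise ValueError(
                f"row {i} ({row.variable}): unknown scaling token {row.scaling!r}"
            )
        if not float(row.p25) <= float(row.p50) <= float(row.p75):
            raise ValueError(f"row {i} ({row.variable}): percentiles not ordered")
        for atom in _atoms(str(row.variable)):
            if not atom:
                raise ValueError(f"row {i}: malformed variable {row.variable!r}")
    df = df.assign(beta=betas)
    kinds = df.region_kind.unique()
    if len(kinds) != 1:
        raise ValueError(f"expected one region per table, got {list(kinds)}")
    return CoefficientTable(df.reset_index(drop=True), str(kinds[0]))


def load_bern_table(region_kind: str) -> CoefficientTable:
    """Load the shipped coefficient table of the final Bern rural or urban
    NO2 model."""
    if region_kind not in ("rural", "urban"):
        raise ValueError("region_kind must be 'rural' or 'urban'")
    ref = resources.files("stlur.data") / f"bern_{region_kind}_model.csv"
    with resources.as_file(ref) as path:
        return parse_coefficient_table(path)


def predict_no2(
    table: CoefficientTable,
    values: dict[str, float],
    period: tuple[dt.date, dt.date] | None = None,
) -> tuple[float, float]:
    """Predict (log NO2, NO2 in ug/m3) from transformed-scale predictor values.

    ``values`` maps each term's atom label to its value on the scale the
    label states (e.g. ``{"log(aqm_no2)": 2.62, "season": 2}``); interaction
    rows use the product of their two atom values.  If ``period`` is given,
    ``season``, ``year`` and ``square(year)`` are derived from it unless
    supplied.  The model has no intercept: all-zero inputs predict log NO2 0,
    i.e. 1 ug/m3.
    """
    vals = dict(values)
    if period is not None:
        from .temporal import season_of, time_trend

        yr, yr2 = time_trend(*period)
        vals.setdefault("season", season_of(*period))
        vals.setdefault("year", yr)
        vals.setdefault("square(year)", yr2)
    needed = {a for v in table.variables for a in _atoms(v)}
    missing = sorted(needed - set(vals))
    if missing:
        raise ValueError(f"missing predictor values: {missing}")
    log_pred = 0.0
    for row in table.rows.itertuples(index=False):
        x = 1.0
        for atom in _atoms(row.variable):
            x *= float(vals[atom])
        log_pred += row.beta * x
    return log_pred, float(np.exp(log_pred))


def per_iqr_effect(table: CoefficientTable, variable: str) -> float:
    """Change in log NO2 when ``variable`` moves from its p25 to its p75
    (or 0 -> 1 for land-use fractions), everything else fixed and interaction
    partners held at 0.  Equals the table's printed estimate."""
    row = table.row(variable)
    atoms = _atoms(variable)
    if len(atoms) == 2:
        # interaction: the effect is scaled on the product column's own IQR
        return float(row.beta * (float(row.p75) - float(row.p25)))
    base = {a: 0.0 for v in table.variables for a in _atoms(v)}
    if row.scaling == "per_0_to_100":
        lo_val, hi_val = 0.0, 1.0
    else:
        lo_val, hi_val = float(row.p25), float(row.p75)
    lo_pred, _ = predict_no2(table, dict(base, **{atoms[0]: lo_val}))
    hi_pred, _ = predict_no2(table, dict(base, **{atoms[0]: hi_val}))
    return float(hi_pred - lo_pred)


@dataclass
class ExposureWindow:
    """A pregnancy-relevant averaging window [start, end)."""

    kind: str  # trimester1|trimester2|trimester3|full_pregnancy|first_year|custom
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} must be after start {self.start}")

    @property
    def days(self) -> int:
        return (self.end - self.start).days


def pregnancy_windows(
    conception: dt.date, delivery: dt.date, first_year: bool = True
) -> list[ExposureWindow]:
    """Standard exposure windows: trimesters (gestational weeks 1-13, 14-27,
    28-delivery), full pregnancy, and optionally the first year of life."""
    if delivery <= conception:
        raise ValueError("delivery must be after conception")
    w13 = conception + dt.timedelta(weeks=13)
    w27 = conception + dt.timedelta(weeks=27)
    windows = [
        ExposureWindow("trimester1", conception, min(w13, delivery)),
        ExposureWindow("full_pregnancy", conception, delivery),
    ]
    if delivery > w13:
        windows.insert(1, ExposureWindow("trimester2", w13, min(w27, delivery)))
    if delivery > w27:
        windows.insert(2, ExposureWindow("trimester3", w27, delivery))
    if first_year:
        windows.append(
            ExposureWindow("first_year", delivery, delivery + dt.timedelta(days=365))
        )
    return windows


def window_exposure(
    predictions: pd.DataFrame, window: ExposureWindow, min_coverage: float = 0.8
) -> float:
    """Day-weighted mean NO2 over the window from period predictions.

    ``predictions`` needs columns ``period_start, period_end, no2``; each
    period contributes its value weighted by the number of its days that fall
    inside the window.  At least ``min_coverage`` of the window's days must be
    covered, otherwise an error reports the coverage fraction.  Splitting a
    period into consecutive sub-periods with the same value leaves the result
    unchanged.
    """
    total_w = 0.0
    total = 0.0
    for row in predictions.itertuples(index=False):
        s = max(pd.Timestamp(row.period_start).date(), window.start)
        e = min(pd.Timestamp(row.period_end).date(), window.end)
        days = (e - s).days
        if days > 0:
            total_w += days
            total += days * float(row.no2)
    coverage = total_w / window.days
    if coverage < min_coverage:
        raise ValueError(
            f"window {window.kind} {window.start}..{window.end}: only "
            f"{coverage:.1%} of days covered (need >= {min_coverage:.0%})"
        )
    return total / total_w
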