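"""Assembly of the per-measurement predictor table.

One row per measurement: the spatial predictors of the site, interpolated to
the calendar year of the period midpoint, merged with the period-averaged
temporal predictors from the site's assigned stations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spatial import spatial_predictor_table
from .synthetic import Region
from .temporal import temporal_predictor_table

__all__ = ["build_predictor_table"]


def build_predictor_table(region: Region, periods: pd.DataFrame) -> pd.DataFrame:
    """Merge spatial (per site-year) and temporal (per period) predictors into
    one row per measurement.

    ``periods`` needs columns ``site_id, period_start, period_end``.
    """
    temporal = temporal_predictor_table(
        region.series,
        periods,
        region.station_of_site(),
        region.aqm_station,
    )
    years = sorted(temporal.midpoint_year.unique())
    spatial = spatial_predictor_table(region.sites, region.layers, years)
    spatial = spatial.rename(columns={"year": "midpoint_year"})
    merged = temporal.merge(spatial, on=["site_id", "midpoint_year"], how="left")
    if merged.isna().any().any():
        bad = merged.loc[merged.isna().any(axis=1), ["site_id", "period_start"]].iloc[0]
        raise ValueError(
            f"missing predictors for site {bad.site_id}, period {bad.period_start}"
        )
    if len(merged) != len(periods):
        raise ValueError("predictor merge changed the number of rows")
    return merged
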