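"""On-disk exchange formats for regions and campaigns.

Sites, measurements and daily series travel as CSV with ISO-8601 dates;
roads and land-use patches as GeoJSON (planar metre coordinates); the
population and dispersion grids as headed CSV.  A saved region directory can
be reloaded into an identical :class:`~stlur.synthetic.Region`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .layers import load_layers, save_layers
from .synthetic import Region, RegionConfig

__all__ = [
    "save_region",
    "load_region",
    "save_measurements",
    "load_measurements",
]

SITE_COLUMNS = ["site_id", "x", "y", "region_kind", "altitude", "site_class"]
MEASUREMENT_COLUMNS = [
    "site_id", "period_start", "period_end", "no2", "sampler", "backyard",
]


def save_region(region: Region, outdir: Path | str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region.sites[SITE_COLUMNS].to_csv(outdir / "sites.csv", index=False)
    region.stations.to_csv(outdir / "stations.csv", index=False)
    save_layers(region.layers, outdir / "layers")
    rows = []
    for (var, station), s in region.series.items():
        frame = pd.DataFrame(
            {"variable": var, "station_id": station,
             "date": s.index.strftime("%Y-%m-%d"), "value": s.to_numpy()}
        )
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(outdir / "daily_series.csv", index=False)


def load_region(indir: Path | str, config: RegionConfig | None = None) -> Region:
    indir = Path(indir)
    sites = pd.read_csv(indir / "sites.csv")
    stations = pd.read_csv(indir / "stations.csv")
    layers = load_layers(indir / "layers")
    long = pd.read_csv(indir / "daily_series.csv", parse_dates=["date"])
    series = {
        (var, st): g.set_index("date")["value"].sort_index()
        for (var, st), g in long.groupby(["variable", "station_id"])
    }
    if config is None:
        config = RegionConfig(region_kind=str(sites.region_kind.iloc[0]))
    return Region(config, sites, layers, series, stations)


def save_measurements(measurements: pd.DataFrame, path: Path | str) -> None:
    measurements[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def load_measurements(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["period_start", "period_end"])
    df["period_start"] = df.period_start.dt.date
    df["period_end"] = df.period_end.dt.date
    return df
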