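"""Synthetic study region and measurement campaigns with known ground truth.

The generator emulates the two Bernese passive-sampler NO2 networks: a rural
network (~101 sites, consecutive 14-day exposure periods, 1998-2009) and an
urban network (~45 sites, calendar-month periods), plus a study-style set of
residence measurements (14-day, 2010-2012) with a multiplicative backyard
bias.  The generating model for measured concentrations reuses the exposure
model's own form,

    log(NO2) = sum_k beta_k * X_k + Normal(0, noise_sd),

with X_k the spatial/temporal predictors computed by the feature modules and
``truth_coefficients`` the generating betas on the log scale, so parameter
recovery by the fitting machinery is exactly testable.  Backyard measurements
are additionally divided by ``backyard_factor`` on the concentration scale
(samplers behind the residence under-read relative to the front-of-house
model).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layers import GeoLayers, Grid, GridStack, LandPatch, Road
from .terms import build_design_matrix, parse_term

__all__ = [
    "ConfigError",
    "RegionConfig",
    "Region",
    "rural_config",
    "urban_config",
    "RURAL_TRUTH",
    "URBAN_TRUTH",
    "RURAL_SITE_CLASSES",
    "URBAN_SITE_CLASSES",
    "campaign_periods",
    "generate_region",
    "generate_measurements",
    "generate_study_measurements",
]


class ConfigError(ValueError):
    """Invalid region configuration; the message names the offending field."""


# Site typology shares of the two regulatory networks.
RURAL_SITE_CLASSES = {
    "near-highway": 0.11,
    "residential-near-major-road": 0.38,
    "rural-near-major-road": 0.24,
    "industrial": 0.02,
    "residential-far": 0.09,
    "rural-far": 0.10,
    "background": 0.06,
}
URBAN_SITE_CLASSES = {
    "near-highway": 0.22,
    "residential-near-major-road": 0.36,
    "medium-traffic": 0.18,
    "low-traffic": 0.13,
    "background": 0.11,
}

# Generating coefficients (log scale, raw predictor units).  Magnitudes echo
# the final Bern models: the background AQM log-NO2 and traffic terms carry
# most of the signal; the near-constant raw-year column plays the baseline
# role of the suppressed intercept.
RURAL_TRUTH: dict[str, float] = {
    "log(aqm_no2)": 0.357,
    "log(dispersion_no2)": 0.104,
    "road_major_len_100": 0.0020,
    "season": 0.0905,
    "road_major_len_100 * season": -6.4e-4,
    "sqrt(traffic_nearest_road)": 0.00146,
    "pop_100": 3.6e-4,
    "temperature": -0.00817,
    "altitude": -3.2e-4,
    "lu_highdens_200": 0.41,
    "year": 9.1e-4,
}
URBAN_TRUTH: dict[str, float] = {
    "log(aqm_no2)": 0.30,
    "log(dispersion_no2)": 0.16,
    "sqrt(vehicles_100)": 0.0035,
    "season": 0.095,
    "sqrt(vehicles_100) * season": -9.0e-4,
    "log(inv_dist_major_road)": 0.11,
    "pop_100": 3.7e-4,
    "temperature": -0.0065,
    "year": 1.18e-3,
}


@dataclass
class RegionConfig:
    region_kind: str = "rural"
    n_sites: int = 101
    extent: float = 30_000.0
    campaign_start: dt.date = dt.date(1998, 1, 5)
    campaign_end: dt.date = dt.date(2009, 12, 28)
    period_length: int | str = 14  # days, or "month" for calendar months
    seed: int = 0
    truth_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(RURAL_TRUTH)
    )
    noise_sd: float = 0.2
    backyard_factor: float = 1.275
    #: fraction of site-periods actually measured (network gaps)
    completeness: float = 0.78
    #: fraction of sites whose sampler sits in the backyard (study-style sets)
    backyard_fraction: float = 0.0
    n_highways: int = 6
    n_major_roads: int = 60
    n_minor_roads: int = 150
    land_cell: float = 1000.0
    pop_cell: float = 500.0
    series_start: dt.date = dt.date(1998, 1, 1)
    series_end: dt.date = dt.date(2012, 12, 31)

    def validate(self) -> None:
        if self.region_kind not in ("rural", "urban"):
            raise ConfigError(f"region_kind must be rural|urban, got {self.region_kind!r}")
        if self.n_sites < 2:
            raise ConfigError(f"n_sites must be >= 2, got {self.n_sites}")
        if self.extent <= 0:
            raise ConfigError(f"extent must be > 0, got {self.extent}")
        if self.period_length != "month" and (
            not isinstance(self.period_length, int) or self.period_length < 1
        ):
            raise ConfigError(f"period_length must be >= 1 day or 'month', got {self.period_length!r}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.backyard_factor <= 0:
            raise ConfigError(f"backyard_factor must be > 0, got {self.backyard_factor}")
        if not 0 < self.completeness <= 1:
            raise ConfigError(f"completeness must be in (0, 1], got {self.completeness}")
        if not 0 <= self.backyard_fraction <= 1:
            raise ConfigError(f"backyard_fraction must be in [0, 1], got {self.backyard_fraction}")
        if self.campaign_end <= self.campaign_start:
            raise ConfigError("campaign_end must be after campaign_start")


def rural_config(**overrides) -> RegionConfig:
    """Default rural network: 101 sites, biweekly periods, ~24.5k measurements."""
    cfg = RegionConfig(**overrides) if overrides else RegionConfig()
    cfg.validate()
    return cfg


def urban_config(**overrides) -> RegionConfig:
    """Default urban network: 45 sites, calendar-month periods, ~4.4k measurements."""
    base = dict(
        region_kind="urban",
        n_sites=45,
        extent=7_000.0,
        campaign_start=dt.date(2001, 1, 1),
        campaign_end=dt.date(2009, 12, 31),
        period_length="month",
        truth_coefficients=dict(URBAN_TRUTH),
        backyard_factor=1.104,
        completeness=0.90,
        n_highways=3,
        n_major_roads=40,
        n_minor_roads=120,
        land_cell=500.0,
        pop_cell=200.0,
    )
    base.update(overrides)
    cfg = RegionConfig(**base)
    cfg.validate()
    return cfg


@dataclass
class Region:
    """A generated study region: sites, GIS layers, daily series, stations."""

    config: RegionConfig
    sites: pd.DataFrame
    layers: GeoLayers
    series: dict[tuple[str, str], pd.Series]
    stations: pd.DataFrame  # station_id, x, y, kind in {aqm, met}

    @property
    def aqm_station(self) -> str:
        return self.stations.loc[self.stations.kind == "aqm", "station_id"].iloc[0]

    def station_of_site(self) -> dict[str, str]:
        """Nearest meteorological station per site (Euclidean distance)."""
        met = self.stations[self.stations.kind == "met"]
        out = {}
        for s in self.sites.itertuples(index=False):
            d2 = (met.x - s.x) ** 2 + (met.y - s.y) ** 2
            out[s.site_id] = met.station_id.iloc[int(np.argmin(d2.to_numpy()))]
        return out


# ---------------------------------------------------------------------------
# region generation
# ---------------------------------------------------------------------------

def _make_roads(cfg: RegionConfig, rng: np.random.Generator) -> list[Road]:
    from shapely.geometry import LineString

    E = cfg.extent
    aadt_years = (2000, 2004, 2008)
    specs = [
        ("highway", cfg.n_highways, 10.7, 0.3),
        ("major", cfg.n_major_roads, 9.1, 0.5),
        ("minor", cfg.n_minor_roads, 6.4, 0.7),
    ]
    roads = []
    for cls, n, mu, sd in specs:
        for _ in range(n):
            if cls == "highway":  # long arteries crossing the region
                x0, y0 = rng.uniform(0, E, 2)
                ang = rng.uniform(0, np.pi)
                dx, dy = np.cos(ang), np.sin(ang)
                p0 = (x0 - dx * E, y0 - dy * E)
                p1 = (x0 + dx * E, y0 + dy * E)
                pts = [np.clip(p0, 0, E), np.clip(p1, 0, E)]
            else:
                length = rng.uniform(0.05, 0.3) * E if cls == "major" else rng.uniform(0.01, 0.08) * E
                x0, y0 = rng.uniform(0, E, 2)
                ang = rng.uniform(0, 2 * np.pi)
                mid = np.array([x0, y0])
                off = np.array([np.cos(ang), np.sin(ang)]) * length / 2
                kink = rng.normal(0, length * 0.1, 2)
                pts = [
                    np.clip(mid - off, 0, E),
                    np.clip(mid + kink, 0, E),
                    np.clip(mid + off, 0, E),
                ]
            base = float(np.exp(rng.normal(mu, sd)))
            aadt = {
                yr: max(base * (1 + 0.01 * (yr - 2004) + rng.normal(0, 0.02)), 1.0)
                for yr in aadt_years
            }
            geom = LineString([tuple(p) for p in pts])
            if geom.length < 1.0:
                continue
            roads.append(Road(geom, cls, aadt))
    return roads


def _make_land_use(cfg: RegionConfig, rng: np.random.Generator) -> list[LandPatch]:
    from shapely.geometry import box

    E, c = cfg.extent, cfg.land_cell
    n = max(int(round(E / c)), 1)
    if cfg.region_kind == "rural":
        classes = ("other", "lowdens", "highdens", "industrial")
        probs = (0.70, 0.20, 0.04, 0.06)
    else:
        classes = ("other", "lowdens", "highdens", "industrial")
        probs = (0.25, 0.35, 0.30, 0.10)
    patches = []
    for iy in range(n):
        for ix in range(n):
            c2000 = classes[rng.choice(len(classes), p=probs)]
            c2006 = (
                classes[rng.choice(len(classes), p=probs)]
                if rng.random() < 0.05
                else c2000
            )
            patches.append(
                LandPatch(box(ix * c, iy * c, (ix + 1) * c, (iy + 1) * c),
                          {2000: c2000, 2006: c2006})
            )
    return patches


def _tile_class(patches: list[LandPatch], cfg: RegionConfig, x: float, y: float) -> str:
    c = cfg.land_cell
    n = max(int(round(cfg.extent / c)), 1)
    ix = min(int(x // c), n - 1)
    iy = min(int(y // c), n - 1)
    return patches[iy * n + ix].cls[2000]


def _make_population(cfg: RegionConfig, patches: list[LandPatch],
                     rng: np.random.Generator) -> Grid:
    c = cfg.pop_cell
    n = max(int(round(cfg.extent / c)), 1)
    scale = (c / 500.0) ** 2  # densities defined per 500 m cell
    lam = {"highdens": 1500.0, "lowdens": 400.0, "industrial": 40.0, "other": 10.0}
    values = np.zeros((n, n))
    for iy in range(n):
        for ix in range(n):
            cls = _tile_class(patches, cfg, (ix + 0.5) * c, (iy + 0.5) * c)
            values[iy, ix] = rng.poisson(lam[cls] * scale)
    return Grid(0.0, 0.0, c, values)


def _segment_distances(px: np.ndarray, py: np.ndarray, road: Road) -> np.ndarray:
    """Min distance from points to the road polyline (vectorised)."""
    coords = np.asarray(road.geom.coords)
    best = np.full(px.shape, np.inf)
    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
        dx, dy = x2 - x1, y2 - y1
        den = dx * dx + dy * dy
        if den == 0:
            d = np.hypot(px - x1, py - y1)
        else:
            t = np.clip(((px - x1) * dx + (py - y1) * dy) / den, 0, 1)
            d = np.hypot(px - (x1 + t * dx), py - (y1 + t * dy))
        best = np.minimum(best, d)
    return best


def _make_dispersion(cfg: RegionConfig, roads: list[Road],
                     rng: np.random.Generator) -> GridStack:
    c = 400.0
    n = max(int(np.ceil(cfg.extent / c)), 1)
    xs = (np.arange(n) + 0.5) * c
    cx, cy = np.meshgrid(xs, xs)
    px, py = cx.ravel(), cy.ravel()
    base = np.full(px.shape, 14.0 if cfg.region_kind == "rural" else 18.0)
    for road in roads:
        if road.road_class == "minor":
            continue
        d = _segment_distances(px, py, road)
        base += 5e-4 * road.aadt[2004] * np.exp(-d / 300.0)
    base += rng.normal(0, 1.0, base.shape)
    base = np.clip(base, 2.0, None).reshape(n, n)
    values = {
        yr: np.clip(base * (1.0 - 0.007 * (yr - 2000)), 1.0, None)
        for yr in range(2000, 2008)
    }
    return GridStack(0.0, 0.0, c, values)


def _altitude_surface(cfg: RegionConfig, x: float, y: float) -> float:
    if cfg.region_kind == "rural":
        return 480.0 + 60.0 * np.sin(x / 7000.0) + 40.0 * np.cos(y / 9000.0)
    return 540.0 + 10.0 * np.sin(x / 3000.0)


def _point_near_road(road: Road, lo: float, hi: float, cfg: RegionConfig,
                     rng: np.random.Generator) -> tuple[float, float]:
    pt = road.geom.interpolate(rng.uniform(0, road.geom.length))
    ang = rng.uniform(0, 2 * np.pi)
    r = rng.uniform(lo, hi)
    x = float(np.clip(pt.x + r * np.cos(ang), 1.0, cfg.extent - 1.0))
    y = float(np.clip(pt.y + r * np.sin(ang), 1.0, cfg.extent - 1.0))
    return x, y


def _make_sites(cfg: RegionConfig, roads: list[Road],
                rng: np.random.Generator) -> pd.DataFrame:
    shares = RURAL_SITE_CLASSES if cfg.region_kind == "rural" else URBAN_SITE_CLASSES
    labels = list(shares)
    classes = [labels[i] for i in rng.choice(len(labels), cfg.n_sites, p=list(shares.values()))]
    highways = [r for r in roads if r.road_class == "highway"]
    majors = [r for r in roads if r.road_class in ("highway", "major")]
    rows = []
    prefix = "R" if cfg.region_kind == "rural" else "U"
    for i, cls in enumerate(classes):
        if "near-highway" in cls and highways:
            x, y = _point_near_road(highways[rng.integers(len(highways))], 20, 80, cfg, rng)
        elif "near-major-road" in cls and majors:
            x, y = _point_near_road(majors[rng.integers(len(majors))], 15, 100, cfg, rng)
        else:
            x, y = rng.uniform(1.0, cfg.extent - 1.0, 2)
        alt = max(_altitude_surface(cfg, x, y) + rng.normal(0, 15.0), 0.0)
        rows.append(
            {
                "site_id": f"{prefix}{i + 1:03d}",
                "x": x,
                "y": y,
                "region_kind": cfg.region_kind,
                "altitude": alt,
                "site_class": cls,
            }
        )
    return pd.DataFrame(rows)


def _seasonal(doy: np.ndarray, peak_doy: float, amp: float) -> np.ndarray:
    return amp * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0, sd, n)
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(1 - phi**2)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def _make_series(cfg: RegionConfig, stations: pd.DataFrame,
                 rng: np.random.Generator) -> dict[tuple[str, str], pd.Series]:
    dates = pd.date_range(cfg.series_start, cfg.series_end, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    n = len(dates)
    series: dict[tuple[str, str], pd.Series] = {}
    aqm = stations.loc[stations.kind == "aqm", "station_id"].iloc[0]
    # rural background NO2: winter-high seasonal cycle, right-skewed
    log_no2 = 2.60 + _seasonal(doy, 15, 0.35) + _ar1(n, 0.6, 0.22, rng)
    series[("aqm_no2", aqm)] = pd.Series(np.exp(log_no2), index=dates)
    for st in stations.loc[stations.kind == "met", "station_id"]:
        off = rng.normal(0, 0.5)
        series[("temperature", st)] = pd.Series(
            9.5 + off + _seasonal(doy, 196, 8.5) + _ar1(n, 0.7, 2.0, rng), index=dates
        )
        series[("pressure", st)] = pd.Series(
            955 + rng.normal(0, 2) + _seasonal(doy, 15, 3.0) + _ar1(n, 0.5, 4.0, rng),
            index=dates,
        )
        series[("humidity", st)] = pd.Series(
            np.clip(75 + _seasonal(doy, 15, 8.0) + _ar1(n, 0.5, 8.0, rng), 20, 100),
            index=dates,
        )
        series[("wind_speed", st)] = pd.Series(
            np.exp(0.8 + _ar1(n, 0.4, 0.35, rng)), index=dates
        )
        series[("cloud_cover", st)] = pd.Series(
            np.clip(4.0 + _seasonal(doy, 15, 1.5) + _ar1(n, 0.4, 1.8, rng), 0, 8),
            index=dates,
        )
        series[("solar_radiation", st)] = pd.Series(
            np.clip(160 * (1 + 0.8 * np.cos(2 * np.pi * (doy - 196) / 365.25))
                    + _ar1(n, 0.4, 30.0, rng), 5, None),
            index=dates,
        )
        series[("boundary_layer_height", st)] = pd.Series(
            np.exp(5.75 + _seasonal(doy, 196, 0.45) + _ar1(n, 0.5, 0.30, rng)),
            index=dates,
        )
    return series


def generate_region(config: RegionConfig) -> Region:
    """Generate sites, GIS layers, stations and daily series for one region.

    Deterministic for a fixed ``config.seed``; different seeds give different
    geographies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    roads = _make_roads(config, rng)
    land_use = _make_land_use(config, rng)
    population = _make_population(config, land_use, rng)
    dispersion = _make_dispersion(config, roads, rng)
    layers = GeoLayers(roads, land_use, population, dispersion)
    sites = _make_sites(config, roads, rng)
    st_rows = [{"station_id": "AQM-1", "kind": "aqm",
                "x": rng.uniform(0, config.extent), "y": rng.uniform(0, config.extent)}]
    for k in range(3):
        st_rows.append({"station_id": f"MET-{k + 1}", "kind": "met",
                        "x": rng.uniform(0, config.extent),
                        "y": rng.uniform(0, config.extent)})
    stations = pd.DataFrame(st_rows)
    series = _make_series(config, stations, rng)
    return Region(config, sites, layers, series, stations)


# ---------------------------------------------------------------------------
# measurement campaigns
# ---------------------------------------------------------------------------

def campaign_periods(config: RegionConfig) -> list[tuple[dt.date, dt.date]]:
    """Measurement periods of the campaign: consecutive non-overlapping
    ``period_length``-day blocks, or calendar months for ``'month'``."""
    periods = []
    if config.period_length == "month":
        d = dt.date(config.campaign_start.year, config.campaign_start.month, 1)
        if d < config.campaign_start:
            d = (d + dt.timedelta(days=32)).replace(day=1)
        while True:
            nxt = (d + dt.timedelta(days=32)).replace(day=1)
            if nxt > config.campaign_end + dt.timedelta(days=1):
                break
            periods.append((d, nxt))
            d = nxt
    else:
        step = dt.timedelta(days=int(config.period_length))
        d = config.campaign_start
        while d + step <= config.campaign_end + dt.timedelta(days=1):
            periods.append((d, d + step))
            d += step
    return periods


def _truth_design(truth: dict[str, float], predictors: pd.DataFrame):
    terms = [parse_term(k) for k in truth]
    if predictors[sorted({v for t in terms for v in t.variables})].isna().any().any():
        bad = predictors.loc[
            predictors[sorted({v for t in terms for v in t.variables})]
            .isna().any(axis=1),
            ["site_id", "period_start"],
        ].iloc[0]
        raise ValueError(
            f"missing predictor for site {bad.site_id} period {bad.period_start}"
        )
    X, names = build_design_matrix(terms, predictors)
    beta = np.array([truth[t.label] for t in terms])
    return X, beta


def generate_measurements(
    region: Region,
    config: RegionConfig | None = None,
    seed: int | None = None,
    predictors: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a measurement campaign from the generating model.

    Returns ``(measurements, predictors)`` aligned row-for-row.  The
    measurement frame carries ``no2`` (ug/m3, backyard bias applied) and the
    noiseless ground truth ``log_truth`` for diagnostics.  Passing a
    precomputed full-campaign ``predictors`` table (from
    :func:`stlur.pipeline.build_predictor_table`) skips the feature
    computation, which makes replicate draws cheap.
    """
    from .pipeline import build_predictor_table

    cfg = config or region.config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if predictors is None:
        periods = campaign_periods(cfg)
        shell = pd.DataFrame(
            [
                {"site_id": s, "period_start": p0, "period_end": p1}
                for s in region.sites.site_id
                for (p0, p1) in periods
            ]
        )
        predictors = build_predictor_table(region, shell)
    keep = (
        rng.random(len(predictors)) < cfg.completeness
        if cfg.completeness < 1
        else np.ones(len(predictors), bool)
    )
    pred = predictors.loc[keep].reset_index(drop=True)
    X, beta = _truth_design(cfg.truth_coefficients, pred)
    log_truth = X @ beta
    noise = rng.normal(0, cfg.noise_sd, len(pred)) if cfg.noise_sd > 0 else 0.0
    log_no2 = log_truth + noise
    backyard_sites = set()
    if cfg.backyard_fraction > 0:
        site_ids = region.sites.site_id.to_numpy()
        mask = rng.random(len(site_ids)) < cfg.backyard_fraction
        backyard_sites = set(site_ids[mask])
    backyard = pred.site_id.isin(backyard_sites).to_numpy()
    no2 = np.exp(log_no2)
    no2[backyard] /= cfg.backyard_factor
    meas = pd.DataFrame(
        {
            "site_id": pred.site_id,
            "period_start": pred.period_start,
            "period_end": pred.period_end,
            "no2": no2,
            "sampler": "palmes",
            "backyard": backyard,
            "log_truth": log_truth,
        }
    )
    return meas, pred


def generate_study_measurements(
    region: Region,
    n_sites: int,
    seed: int,
    start: dt.date = dt.date(2010, 1, 4),
    end: dt.date = dt.date(2012, 12, 17),
    backyard_fraction: float = 26 / 57,
    period_days: int = 14,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Residence-style external-validation set: one 14-day Passam measurement
    per home, scattered over the region, a share of them in the backyard.

    Returns ``(sites, measurements, predictors)``.
    """
    from .pipeline import build_predictor_table

    cfg = region.config
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        x, y = rng.uniform(1.0, cfg.extent - 1.0, 2)
        rows.append(
            {
                "site_id": f"S{i + 1:04d}",
                "x": x,
                "y": y,
                "region_kind": cfg.region_kind,
                "altitude": max(_altitude_surface(cfg, x, y) + rng.normal(0, 15.0), 0.0),
                "site_class": "residence",
            }
        )
    sites = pd.DataFrame(rows)
    max_start = (end - start).days - period_days
    offsets = rng.integers(0, max_start + 1, n_sites)
    shell = pd.DataFrame(
        {
            "site_id": sites.site_id,
            "period_start": [start + dt.timedelta(days=int(o)) for o in offsets],
        }
    )
    shell["period_end"] = shell.period_start + dt.timedelta(days=period_days)
    study_region = Region(cfg, sites, region.layers, region.series, region.stations)
    pred = build_predictor_table(study_region, shell)
    X, beta = _truth_design(cfg.truth_coefficients, pred)
    log_truth = X @ beta
    log_no2 = log_truth + rng.normal(0, cfg.noise_sd, len(pred))
    backyard = rng.random(n_sites) < backyard_fraction
    no2 = np.exp(log_no2)
    no2[backyard] /= cfg.backyard_factor
    meas = pd.DataFrame(
        {
            "site_id": pred.site_id,
            "period_start": pred.period_start,
            "period_end": pred.period_end,
            "no2": no2,
            "sampler": "passam",
            "backyard": backyard,
            "log_truth": log_truth,
        }
    )
    return sites, meas, pred
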