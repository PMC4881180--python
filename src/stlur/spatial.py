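"""Spatial predictors: buffer aggregates, nearest-road metrics, dispersion NO2.

Every spatial predictor is evaluated on a closed disc of one of the standard
buffer radii (50, 100, 200, 300, 500, 1000 m) around the site, using exact
geometric clipping.  Source layers available for several years (traffic
counts, land use, dispersion NO2) are linearly interpolated to the
measurement year and held constant beyond their first/last source year.

The canonical predictor names produced by :func:`spatial_predictor_table`:

====================  =====================================================
``road_major_len_R``  total clipped length (m) of major roads in R m buffer
``vehicles_R``        summed AADT (vehicles/day) of segments crossing buffer
``pop_R``             area-weighted population count in R m buffer
``lu_CLS_R``          land-use fraction (0-1) of class CLS in R m buffer
``dist_major_road``   distance (m, floored at 5) to the nearest major road
``inv_dist_major_road``  1/distance (1/m) for the log(1/d) model term
``traffic_nearest_road`` AADT on the nearest major road
``dispersion_no2``    annual dispersion-model NO2 (ug/m3) at the site
``altitude``          site altitude (m)
====================  =====================================================
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .layers import (
    GeoLayers,
    Grid,
    GridStack,
    LAND_USE_CLASSES,
    LandPatch,
    MAJOR_ROAD_CLASSES,
    Road,
)

__all__ = [
    "BUFFER_RADII",
    "DISTANCE_FLOOR_M",
    "interpolate_layer",
    "land_use_fraction",
    "road_length_in_buffer",
    "vehicles_in_buffer",
    "nearest_major_road",
    "population_in_buffer",
    "dispersion_no2_at",
    "spatial_predictor_table",
]

BUFFER_RADII = (50, 100, 200, 300, 500, 1000)
#: distance floor before reciprocal/log transforms, to keep log(1/d) finite
DISTANCE_FLOOR_M = 5.0
_QUAD_SEGS = 64  # disc approximation: relative area error ~1e-4


def _disc(x: float, y: float, radius: float):
    if radius <= 0:
        raise ValueError(f"buffer radius must be positive, got {radius}")
    return Point(x, y).buffer(radius, quad_segs=_QUAD_SEGS)


def interpolate_layer(values_by_year: Mapping[int, object], year: float):
    """Linear interpolation of annual layer values to ``year``.

    Exact at source years, linear between bracketing source years and
    constant beyond the first/last available year.  Works elementwise on
    scalars and arrays.
    """
    if not values_by_year:
        raise ValueError("no source years available")
    years = sorted(values_by_year)
    if year <= years[0]:
        return values_by_year[years[0]]
    if year >= years[-1]:
        return values_by_year[years[-1]]
    hi = next(y for y in years if y >= year)
    lo = years[years.index(hi) - 1] if hi != year else hi
    if hi == year:
        return values_by_year[hi]
    w = (year - lo) / (hi - lo)
    a, b = values_by_year[lo], values_by_year[hi]
    return (1 - w) * np.asarray(a, float) + w * np.asarray(b, float) if isinstance(
        a, np.ndarray
    ) else (1 - w) * a + w * b


def _candidate_patches(layers_or_patches, disc) -> Iterable[LandPatch]:
    if isinstance(layers_or_patches, GeoLayers):
        tree = layers_or_patches.patch_tree()
        idx = tree.query(disc)
        return [layers_or_patches.land_use[i] for i in idx]
    return layers_or_patches


def land_use_fraction(
    patches: Sequence[LandPatch] | GeoLayers,
    x: float,
    y: float,
    radius: float,
    cls: str,
    year: float,
) -> float:
    """Fraction (0-1) of the disc covered by land-use class ``cls``.

    The fraction is computed at each source year of the land-use layer and
    linearly interpolated to ``year``.
    """
    if cls not in LAND_USE_CLASSES:
        raise ValueError(f"unknown land-use class {cls!r}; known: {LAND_USE_CLASSES}")
    disc = _disc(x, y, radius)
    cand = list(_candidate_patches(patches, disc))
    source_years = sorted({yr for p in cand for yr in p.cls}) or [int(year)]
    frac_by_year: dict[int, float] = {}
    for yr in source_years:
        area = 0.0
        for p in cand:
            if p.cls.get(yr) == cls:
                area += p.geom.intersection(disc).area
        frac_by_year[yr] = area / disc.area
    return float(interpolate_layer(frac_by_year, year))


def _candidate_roads(roads_or_layers, geom) -> list[Road]:
    if isinstance(roads_or_layers, GeoLayers):
        idx = roads_or_layers.road_tree().query(geom)
        return [roads_or_layers.roads[i] for i in idx]
    return list(roads_or_layers)


def _road_classes(road_class) -> tuple[str, ...]:
    if road_class is None:
        return ("highway", "major", "minor")
    if road_class == "major":
        return MAJOR_ROAD_CLASSES
    if isinstance(road_class, str):
        return (road_class,)
    return tuple(road_class)


def road_length_in_buffer(
    roads: Sequence[Road] | GeoLayers,
    x: float,
    y: float,
    radius: float,
    road_class: str | Sequence[str] | None = "major",
) -> float:
    """Total clipped length (m) of roads of the class inside the disc.

    ``road_class='major'`` covers both highways and major roads.
    """
    disc = _disc(x, y, radius)
    classes = _road_classes(road_class)
    total = 0.0
    for r in _candidate_roads(roads, disc):
        if r.road_class in classes:
            total += r.geom.intersection(disc).length
    return total


def vehicles_in_buffer(
    roads: Sequence[Road] | GeoLayers, x: float, y: float, radius: float, year: float
) -> float:
    """Summed annual-average daily traffic over distinct segments crossing the
    disc (a count-of-vehicles definition, not an AADT-by-length load)."""
    disc = _disc(x, y, radius)
    total = 0.0
    for r in _candidate_roads(roads, disc):
        if r.geom.intersects(disc):
            total += float(interpolate_layer(r.aadt, year))
    return total


def nearest_major_road(
    roads: Sequence[Road] | GeoLayers, x: float, y: float, year: float
) -> tuple[float, float]:
    """Distance (m) to the nearest major road and that road's traffic.

    The distance is floored at ``DISTANCE_FLOOR_M`` so that downstream
    reciprocal/log transforms stay finite for on-road sites.
    """
    pt = Point(x, y)
    road_list = roads.roads if isinstance(roads, GeoLayers) else list(roads)
    best_d, best_road = np.inf, None
    for r in road_list:
        if r.road_class not in MAJOR_ROAD_CLASSES:
            continue
        d = pt.distance(r.geom)
        if d < best_d:
            best_d, best_road = d, r
    if best_road is None:
        raise ValueError(
            "no major road in the region; treat nearest-road predictors as missing"
        )
    return max(best_d, DISTANCE_FLOOR_M), float(interpolate_layer(best_road.aadt, year))


def population_in_buffer(grid: Grid, x: float, y: float, radius: float) -> float:
    """Area-weighted population count in the disc: each cell contributes
    count * overlap_area / cell_area."""
    disc = _disc(x, y, radius)
    ny, nx = grid.shape
    c = grid.cell
    ix0 = max(int((x - radius - grid.x0) // c), 0)
    ix1 = min(int((x + radius - grid.x0) // c) + 1, nx)
    iy0 = max(int((y - radius - grid.y0) // c), 0)
    iy1 = min(int((y + radius - grid.y0) // c) + 1, ny)
    total = 0.0
    cell_area = c * c
    for iy in range(iy0, iy1):
        for ix in range(ix0, ix1):
            count = grid.values[iy, ix]
            if count == 0:
                continue
            cell = box(
                grid.x0 + ix * c, grid.y0 + iy * c,
                grid.x0 + (ix + 1) * c, grid.y0 + (iy + 1) * c,
            )
            total += count * cell.intersection(disc).area / cell_area
    return total


def dispersion_no2_at(stack: GridStack, x: float, y: float, year: float) -> float:
    """Annual dispersion-model NO2 (ug/m3) of the containing 400 m cell,
    linearly interpolated between available years and constant outside the
    modelled year range."""
    years = stack.years
    iy, ix = stack.grid(years[0]).cell_index(x, y)
    vals = {yr: float(stack.values[yr][iy, ix]) for yr in years}
    return float(interpolate_layer(vals, year))


def spatial_predictor_table(
    sites: pd.DataFrame,
    layers: GeoLayers,
    years: Sequence[int],
    radii: Sequence[int] = BUFFER_RADII,
    lu_classes: Sequence[str] = LAND_USE_CLASSES,
) -> pd.DataFrame:
    """Spatial predictor row per (site, year).

    Geometry (clipping, intersection, distances) is computed once per site;
    only year-dependent attributes (traffic, land-use class, dispersion NO2)
    vary across the requested years, via linear interpolation.

    ``sites`` needs columns ``site_id, x, y, altitude``.
    """
    aadt_years = sorted({yr for r in layers.roads for yr in r.aadt})
    lu_years = sorted({yr for p in layers.land_use for yr in p.cls})
    rows = []
    for site in sites.itertuples(index=False):
        x, y = float(site.x), float(site.y)
        static: dict[str, float] = {}
        per_year_attrs: dict[str, dict[int, float]] = {}
        for r in radii:
            disc = _disc(x, y, r)
            cand_roads = _candidate_roads(layers, disc)
            major_len = sum(
                rd.geom.intersection(disc).length
                for rd in cand_roads
                if rd.road_class in MAJOR_ROAD_CLASSES
            )
            static[f"road_major_len_{r}"] = major_len
            crossing = [rd for rd in cand_roads if rd.geom.intersects(disc)]
            per_year_attrs[f"vehicles_{r}"] = {
                yr: sum(rd.aadt.get(yr, 0.0) for rd in crossing) for yr in aadt_years
            }
            static[f"pop_{r}"] = population_in_buffer(layers.population, x, y, r)
            cand_patches = list(_candidate_patches(layers, disc))
            inter = [(p, p.geom.intersection(disc).area) for p in cand_patches]
            for cls in lu_classes:
                per_year_attrs[f"lu_{cls}_{r}"] = {
                    yr: sum(a for p, a in inter if p.cls.get(yr) == cls) / disc.area
                    for yr in lu_years
                }
        pt = Point(x, y)
        dists = [
            (pt.distance(rd.geom), rd)
            for rd in layers.roads
            if rd.road_class in MAJOR_ROAD_CLASSES
        ]
        if not dists:
            raise ValueError("no major road in the region")
        dmin, nearest = min(dists, key=lambda t: t[0])
        dmin = max(dmin, DISTANCE_FLOOR_M)
        static["dist_major_road"] = dmin
        static["inv_dist_major_road"] = 1.0 / dmin
        per_year_attrs["traffic_nearest_road"] = dict(nearest.aadt)
        iy, ix = layers.dispersion.grid(layers.dispersion.years[0]).cell_index(x, y)
        per_year_attrs["dispersion_no2"] = {
            yr: float(layers.dispersion.values[yr][iy, ix])
            for yr in layers.dispersion.years
        }
        for target_year in years:
            row = {"site_id": site.site_id, "year": int(target_year)}
            row.update(static)
            for name, by_year in per_year_attrs.items():
                row[name] = float(interpolate_layer(by_year, target_year))
            row["altitude"] = float(site.altitude)
            rows.append(row)
    return pd.DataFrame(rows)
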