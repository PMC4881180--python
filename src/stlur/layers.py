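"""Geometric layer containers for the study region, with GeoJSON/CSV I/O.

All coordinates live in a local planar frame in metres (no CRS handling).
Time-varying attributes (annual average daily traffic, land-use class,
dispersion-model NO2) are stored per source year and interpolated to the
measurement year downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Polygon, mapping, shape

__all__ = [
    "Road",
    "LandPatch",
    "Grid",
    "GridStack",
    "GeoLayers",
    "ROAD_CLASSES",
    "LAND_USE_CLASSES",
    "MAJOR_ROAD_CLASSES",
]

ROAD_CLASSES = ("highway", "major", "minor")
#: classes counted as "major roads" in distance/length predictors
MAJOR_ROAD_CLASSES = ("highway", "major")
LAND_USE_CLASSES = ("highdens", "lowdens", "industrial", "other")


@dataclass
class Road:
    """A polyline road segment with per-source-year traffic (vehicles/day)."""

    geom: LineString
    road_class: str
    aadt: dict[int, float]

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(f"unknown road class {self.road_class!r}")
        for yr, v in self.aadt.items():
            if v < 0:
                raise ValueError(f"negative traffic {v} in year {yr}")


@dataclass
class LandPatch:
    """A land-use polygon with a class label per source year."""

    geom: Polygon
    cls: dict[int, str]

    def __post_init__(self) -> None:
        for yr, c in self.cls.items():
            if c not in LAND_USE_CLASSES:
                raise ValueError(f"unknown land-use class {c!r} (year {yr})")


@dataclass
class Grid:
    """A regular grid of values anchored at (x0, y0); values[iy, ix]."""

    x0: float
    y0: float
    cell: float
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.values.shape
        return self.x0, self.y0, self.x0 + nx * self.cell, self.y0 + ny * self.cell

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        x0, y0, x1, y1 = self.extent()
        if not (x0 <= x < x1 and y0 <= y < y1):
            raise ValueError(f"point ({x}, {y}) outside grid extent {self.extent()}")
        return int((y - self.y0) // self.cell), int((x - self.x0) // self.cell)


@dataclass
class GridStack:
    """A :class:`Grid` geometry shared by several annual value layers."""

    x0: float
    y0: float
    cell: float
    values: dict[int, np.ndarray]

    def grid(self, year: int) -> Grid:
        return Grid(self.x0, self.y0, self.cell, self.values[year])

    @property
    def years(self) -> list[int]:
        return sorted(self.values)


@dataclass
class GeoLayers:
    """All spatial source layers of a study region."""

    roads: list[Road]
    land_use: list[LandPatch]
    population: Grid
    dispersion: GridStack
    _road_tree: object = field(default=None, repr=False, compare=False)
    _patch_tree: object = field(default=None, repr=False, compare=False)

    def road_tree(self):
        from shapely.strtree import STRtree

        if self._road_tree is None:
            self._road_tree = STRtree([r.geom for r in self.roads])
        return self._road_tree

    def patch_tree(self):
        from shapely.strtree import STRtree

        if self._patch_tree is None:
            self._patch_tree = STRtree([p.geom for p in self.land_use])
        return self._patch_tree


# ---------------------------------------------------------------------------
# serialization: roads and land use as GeoJSON, grids as CSV
# ---------------------------------------------------------------------------

def roads_to_geojson(roads: list[Road]) -> dict:
    feats = []
    for r in roads:
        props = {"road_class": r.road_class}
        props.update({f"aadt_{yr}": v for yr, v in sorted(r.aadt.items())})
        feats.append(
            {"type": "Feature", "geometry": mapping(r.geom), "properties": props}
        )
    return {"type": "FeatureCollection", "features": feats}


def roads_from_geojson(doc: dict) -> list[Road]:
    out = []
    for f in doc["features"]:
        props = f["properties"]
        aadt = {
            int(k.split("_")[1]): float(v)
            for k, v in props.items()
            if k.startswith("aadt_")
        }
        out.append(Road(shape(f["geometry"]), props["road_class"], aadt))
    return out


def land_use_to_geojson(patches: list[LandPatch]) -> dict:
    feats = []
    for p in patches:
        props = {f"luclass_{yr}": c for yr, c in sorted(p.cls.items())}
        feats.append(
            {"type": "Feature", "geometry": mapping(p.geom), "properties": props}
        )
    return {"type": "FeatureCollection", "features": feats}


def land_use_from_geojson(doc: dict) -> list[LandPatch]:
    out = []
    for f in doc["features"]:
        cls = {
            int(k.split("_")[1]): v
            for k, v in f["properties"].items()
            if k.startswith("luclass_")
        }
        out.append(LandPatch(shape(f["geometry"]), cls))
    return out


def grid_to_csv(grid: Grid, path: Path) -> None:
    ny, nx = grid.shape
    with open(path, "w") as fh:
        fh.write(f"# x0={grid.x0} y0={grid.y0} cell={grid.cell} ny={ny} nx={nx}\n")
        np.savetxt(fh, grid.values, delimiter=",")


def grid_from_csv(path: Path) -> Grid:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    return Grid(float(meta["x0"]), float(meta["y0"]), float(meta["cell"]), values)


def save_layers(layers: GeoLayers, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "roads.geojson").write_text(json.dumps(roads_to_geojson(layers.roads)))
    (outdir / "land_use.geojson").write_text(
        json.dumps(land_use_to_geojson(layers.land_use))
    )
    grid_to_csv(layers.population, outdir / "population.csv")
    for yr in layers.dispersion.years:
        grid_to_csv(layers.dispersion.grid(yr), outdir / f"dispersion_{yr}.csv")


def load_layers(indir: Path) -> GeoLayers:
    indir = Path(indir)
    roads = roads_from_geojson(json.loads((indir / "roads.geojson").read_text()))
    land_use = land_use_from_geojson(
        json.loads((indir / "land_use.geojson").read_text())
    )
    population = grid_from_csv(indir / "population.csv")
    disp_values: dict[int, np.ndarray] = {}
    x0 = y0 = cell = None
    for p in sorted(indir.glob("dispersion_*.csv")):
        yr = int(p.stem.split("_")[1])
        g = grid_from_csv(p)
        disp_values[yr] = g.values
        x0, y0, cell = g.x0, g.y0, g.cell
    return GeoLayers(
        roads, land_use, population, GridStack(x0, y0, cell, disp_values)
    )
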