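"""Buffer geometry against Monte-Carlo and brute-force oracles."""

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon, box

from stlur.layers import Grid, GridStack, LandPatch, Road
from stlur.spatial import (
    dispersion_no2_at,
    interpolate_layer,
    land_use_fraction,
    nearest_major_road,
    population_in_buffer,
    road_length_in_buffer,
    vehicles_in_buffer,
)


def road(coords, cls="major", aadt=5000.0, year=2004):
    return Road(LineString(coords), cls, {year: aadt})


# --- land use ---------------------------------------------------------------

def test_land_use_fraction_empty_and_full_cover():
    patches = [LandPatch(box(-1000, -1000, 1000, 1000), {2000: "highdens"})]
    assert land_use_fraction(patches, 0, 0, 100, "lowdens", 2000) == 0.0
    assert land_use_fraction(patches, 0, 0, 100, "highdens", 2000) == pytest.approx(
        1.0, abs=1e-9
    )


def test_land_use_fraction_unknown_class_lists_known():
    with pytest.raises(ValueError, match="highdens"):
        land_use_fraction([], 0, 0, 100, "bogus", 2000)


def test_half_plane_through_centre_matches_monte_carlo():
    patches = [LandPatch(box(0, -500, 500, 500), {2000: "industrial"})]
    frac = land_use_fraction(patches, 0, 0, 100, "industrial", 2000)
    rng = np.random.default_rng(0)
    pts = rng.uniform(-100, 100, (1_000_000, 2))
    inside = np.hypot(pts[:, 0], pts[:, 1]) <= 100
    mc = np.mean(pts[inside, 0] >= 0)
    assert frac == pytest.approx(0.5, abs=1e-3)
    assert frac == pytest.approx(mc, abs=2e-3)


def test_land_use_fraction_interpolates_between_source_years():
    patches = [
        LandPatch(box(-500, -500, 500, 500), {2000: "highdens", 2006: "lowdens"})
    ]
    assert land_use_fraction(patches, 0, 0, 100, "highdens", 2003) == pytest.approx(
        0.5, abs=1e-9
    )


def test_exhaustive_fractions_sum_to_one(small_region):
    layers = small_region.layers
    rng = np.random.default_rng(1)
    for _ in range(5):
        x, y = rng.uniform(2000, 18000, 2)
        r = rng.choice([100, 300, 1000])
        total = sum(
            land_use_fraction(layers, x, y, r, cls, 2003)
            for cls in ("highdens", "lowdens", "industrial", "other")
        )
        assert total == pytest.approx(1.0, abs=1e-6)


# --- roads ------------------------------------------------------------------

def test_road_length_no_roads_and_diameter_chord():
    assert road_length_in_buffer([], 0, 0, 100) == 0.0
    chord = [road([(-500, 0), (500, 0)])]
    assert road_length_in_buffer(chord, 0, 0, 100) == pytest.approx(200.0, abs=0.05)


def test_road_length_matches_dense_sampling_oracle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        segs = [
            road([tuple(rng.uniform(-300, 300, 2)), tuple(rng.uniform(-300, 300, 2))])
            for _ in range(4)
        ]
        r = float(rng.uniform(50, 200))
        got = road_length_in_buffer(segs, 0, 0, r)
        # oracle: discretize each segment very finely, sum step lengths inside
        total = 0.0
        for s in segs:
            (x1, y1), (x2, y2) = s.geom.coords
            n = 20001
            t = np.linspace(0, 1, n)
            xs, ys = x1 + t * (x2 - x1), y1 + t * (y2 - y1)
            inside = np.hypot(xs, ys) <= r
            mids = (inside[:-1] & inside[1:]).sum()
            total += mids * s.geom.length / (n - 1)
        assert got == pytest.approx(total, rel=2e-3, abs=0.5)


def test_vehicles_in_buffer_enumeration():
    assert vehicles_in_buffer([], 0, 0, 50, 2004) == 0.0
    one = [road([(-10, -10), (10, 10)], aadt=5000)]
    assert vehicles_in_buffer(one, 0, 0, 50, 2004) == 5000.0
    three = [
        road([(-10, 0), (10, 0)], aadt=100),
        road([(0, -10), (0, 10)], aadt=200),
        road([(-5, -5), (5, 5)], aadt=300),
    ]
    assert vehicles_in_buffer(three, 0, 0, 50, 2004) == 600.0
    far = [road([(900, 900), (950, 950)], aadt=999)]
    assert vehicles_in_buffer(three + far, 0, 0, 50, 2004) == 600.0


def test_nearest_major_road_floor_argmin_and_brute_force():
    roads = [
        road([(-100, 50), (100, 50)], aadt=1000),
        road([(-100, 150), (100, 150)], aadt=9000),
    ]
    d, t = nearest_major_road(roads, 0, 0, 2004)
    assert (d, t) == (50.0, 1000.0)
    on_road = nearest_major_road(roads, 0, 50, 2004)
    assert on_road[0] == 5.0  # floored
    rng = np.random.default_rng(3)
    segs = [
        road([tuple(rng.uniform(-500, 500, 2)), tuple(rng.uniform(-500, 500, 2))],
             aadt=float(i + 1))
        for i in range(20)
    ]
    d, t = nearest_major_road(segs, 10, -20, 2004)
    from shapely.geometry import Point

    dists = [Point(10, -20).distance(s.geom) for s in segs]
    j = int(np.argmin(dists))
    assert d == pytest.approx(max(dists[j], 5.0))
    assert t == float(j + 1)


def test_nearest_major_road_requires_major_roads():
    with pytest.raises(ValueError, match="missing"):
        nearest_major_road([road([(0, 0), (1, 1)], cls="minor")], 0, 0, 2004)


# --- population -------------------------------------------------------------

def test_population_empty_uniform_and_single_cell():
    empty = Grid(0, 0, 100, np.zeros((10, 10)))
    assert population_in_buffer(empty, 500, 500, 150) == 0.0
    density = 0.02  # people per m^2
    uniform = Grid(0, 0, 100, np.full((40, 40), density * 100 * 100))
    got = population_in_buffer(uniform, 2000, 2000, 300)
    assert got == pytest.approx(density * np.pi * 300**2, rel=0.01)
    single = Grid(0, 0, 1000, np.array([[800.0]]))
    got = population_in_buffer(single, 500, 500, 100)
    assert got == pytest.approx(800 * np.pi * 100**2 / 1000**2, rel=1e-3)


# --- dispersion and annual interpolation ------------------------------------

def test_dispersion_direct_interpolated_and_extrapolated():
    vals = {
        2000: np.array([[10.0, 20.0]]),
        2002: np.array([[30.0, 40.0]]),
    }
    stack = GridStack(0, 0, 400, vals)
    assert dispersion_no2_at(stack, 100, 100, 2000) == 10.0
    assert dispersion_no2_at(stack, 500, 100, 2001) == pytest.approx(30.0)
    assert dispersion_no2_at(stack, 100, 100, 1998) == 10.0
    assert dispersion_no2_at(stack, 100, 100, 2010) == 30.0
    with pytest.raises(ValueError, match="outside"):
        dispersion_no2_at(stack, 5000, 100, 2000)


def test_interpolate_layer_examples():
    with pytest.raises(ValueError):
        interpolate_layer({}, 2000)
    assert interpolate_layer({2003: 7.0}, 1999) == 7.0
    aadt = {2000: 1000.0, 2008: 2000.0}
    assert interpolate_layer(aadt, 2004) == pytest.approx(1500.0)
    assert interpolate_layer(aadt, 2002) == pytest.approx(1250.0)
    assert interpolate_layer(aadt, 2000) == 1000.0


# --- monotonicity property ---------------------------------------------------

def test_buffer_aggregates_nondecreasing_in_radius(small_region):
    layers = small_region.layers
    rng = np.random.default_rng(4)
    radii = [50, 100, 200, 300, 500, 1000]
    for _ in range(5):
        x, y = rng.uniform(2000, 18000, 2)
        lengths = [road_length_in_buffer(layers, x, y, r) for r in radii]
        vehicles = [vehicles_in_buffer(layers, x, y, r, 2004) for r in radii]
        pop = [population_in_buffer(layers.population, x, y, r) for r in radii]
        for seq in (lengths, vehicles, pop):
            assert all(b >= a - 1e-9 for a, b in zip(seq, seq[1:]))
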