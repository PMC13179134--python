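"""Exact distance geometry and regional assignment.

The nearest-distance path is validated against a plain-Python
point-to-primitive oracle and against shapely's independent geometry
engine, plus rigid-motion invariance and monotonicity-under-union
properties.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marrowmap import (CellPattern, Primitive, StructureSet, assign_region,
                       nearest_distance, region_proportions)
from marrowmap.distances import mask_distances, min_distances
from marrowmap.errors import (EmptyStructureError, OutOfBoundsError,
                              ValidationError)
from .conftest import uniform_pattern


def brute_force_distances(points, structures):
    """Plain-loop point-to-primitive surface distance (test oracle)."""
    out = np.empty(len(points))
    for i, (px, py) in enumerate(points):
        best = np.inf
        for prim in structures.primitives:
            if prim.kind == "segment":
                (ax, ay), (bx, by) = prim.coordinates
                abx, aby = bx - ax, by - ay
                denom = abx * abx + aby * aby
                if denom == 0:
                    t = 0.0
                else:
                    t = ((px - ax) * abx + (py - ay) * aby) / denom
                    t = min(1.0, max(0.0, t))
                cx, cy = ax + t * abx, ay + t * aby
                d = np.hypot(px - cx, py - cy)
            else:
                cx, cy = prim.coordinates
                d = np.hypot(px - cx, py - cy)
            best = min(best, max(d - prim.radius_um, 0.0))
        out[i] = best
    return out


def random_structures(rng, n_seg=8, n_disk=4, box=100.0):
    prims = []
    for _ in range(n_seg):
        prims.append(Primitive(kind="segment",
                               coordinates=rng.uniform(0, box, (2, 2)),
                               radius_um=float(rng.uniform(0, 4))))
    for _ in range(n_disk):
        prims.append(Primitive(kind="disk",
                               coordinates=rng.uniform(0, box, 2),
                               radius_um=float(rng.uniform(0, 6))))
    return StructureSet(primitives=prims, label="vessel")


@pytest.mark.parametrize("seed", range(5))
def test_nearest_distance_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    structs = random_structures(rng, n_seg=20, n_disk=5)
    pts = rng.uniform(0, 100, (50, 2))
    cells = CellPattern(pts[:, 0], pts[:, 1])
    res = nearest_distance(cells, structs)
    assert np.allclose(res.nearest_distance_um,
                       brute_force_distances(pts, structs), atol=1e-9)


def test_nearest_distance_matches_shapely():
    shapely = pytest.importorskip("shapely")
    from shapely.geometry import LineString, Point
    rng = np.random.default_rng(11)
    structs = random_structures(rng)
    pts = rng.uniform(0, 100, (40, 2))
    cells = CellPattern(pts[:, 0], pts[:, 1])
    ours = nearest_distance(cells, structs).nearest_distance_um
    geoms = []
    for prim in structs.primitives:
        base = LineString(prim.coordinates) if prim.kind == "segment" \
            else Point(prim.coordinates)
        geoms.append((base, prim.radius_um))
    theirs = np.array([
        min(max(g.distance(Point(p)) - r, 0.0) for g, r in geoms)
        for p in pts])
    assert np.allclose(ours, theirs, atol=1e-9)


def test_surface_distance_examples():
    structs = StructureSet(primitives=[
        Primitive(kind="point", coordinates=[0.0, 0.0], radius_um=4.0)])
    cells = CellPattern([10.0, 4.0, 1.0], [0.0, 0.0, 0.0])
    d = nearest_distance(cells, structs).nearest_distance_um
    assert d[0] == pytest.approx(6.0)          # 10 - 4
    assert d[1] == 0.0                         # exactly on the surface
    assert d[2] == 0.0                         # inside the lumen -> floored


def test_tie_broken_by_lowest_index():
    structs = StructureSet(primitives=[
        Primitive(kind="point", coordinates=[0.0, 0.0]),
        Primitive(kind="point", coordinates=[2.0, 0.0])])
    cells = CellPattern([1.0], [0.0])  # equidistant from both
    res = nearest_distance(cells, structs)
    assert res.nearest_structure_index[0] == 0


def test_empty_structure_set_is_an_error():
    cells = CellPattern([1.0], [1.0])
    with pytest.raises(EmptyStructureError):
        nearest_distance(cells, StructureSet(primitives=[]))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000),
       st.floats(-50, 50), st.floats(-50, 50),
       st.floats(0, 2 * np.pi))
def test_rigid_motion_invariance(seed, dx, dy, angle):
    """Translating and rotating cells and structures together preserves
    every nearest distance to 1e-9."""
    rng = np.random.default_rng(seed)
    structs = random_structures(rng, n_seg=4, n_disk=2)
    pts = rng.uniform(0, 100, (15, 2))
    base = min_distances(pts, structs)[0]
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])

    def xf(a):
        return a @ rot.T + [dx, dy]

    moved = StructureSet(primitives=[
        Primitive(kind=p.kind, coordinates=xf(np.atleast_2d(p.coordinates))
                  if p.kind == "segment" else xf(p.coordinates[None])[0],
                  radius_um=p.radius_um)
        for p in structs.primitives], label=structs.label)
    after = min_distances(xf(pts), moved)[0]
    assert np.allclose(base, after, atol=1e-9)


def test_adding_structures_never_increases_distance():
    rng = np.random.default_rng(3)
    structs = random_structures(rng, n_seg=6, n_disk=3)
    pts = rng.uniform(0, 100, (30, 2))
    d_all = min_distances(pts, structs)[0]
    subset = StructureSet(primitives=structs.primitives[:4],
                          label="vessel")
    d_sub = min_distances(pts, subset)[0]
    assert np.all(d_all <= d_sub + 1e-12)


def test_mask_distance_transform_close_to_exact(small_section):
    geometry, vessels, _ = small_section
    cells = uniform_pattern(geometry, 200, seed=9)
    exact = nearest_distance(cells, vessels).nearest_distance_um
    mask = vessels.rasterize(geometry)
    approx = mask_distances(cells, mask, geometry.resolution_um)
    # raster path is documented as accurate to about one pixel; allow a
    # little extra because rasterization itself pads by half a pixel
    assert np.max(np.abs(exact - approx)) <= 2.5 * geometry.resolution_um


# --------------------------- region assignment ----------------------------

def test_region_boundaries_are_half_open(small_section):
    geometry, _, _ = small_section
    b1, b2 = geometry.region_bounds_um
    cells = CellPattern([0.0, b1, b2, geometry.length_um],
                        [1.0, 1.0, 1.0, 1.0])
    labels = assign_region(cells, geometry).labels
    assert list(labels) == ["PM", "CM", "DM", "DM"]


def test_out_of_bounds_cells_reported_with_rows(small_section):
    geometry, _, _ = small_section
    cells = CellPattern([-1.0, 5.0, geometry.length_um + 2], [1, 1, 1])
    with pytest.raises(OutOfBoundsError) as exc:
        assign_region(cells, geometry)
    assert exc.value.rows == [0, 2]


def test_uniform_cells_match_area_fractions(small_section):
    """1,000 uniform cells split over regions like the marrow area does
    (chi-square goodness of fit, alpha = 0.01)."""
    from scipy import stats as sps
    geometry, _, _ = small_section
    cells = uniform_pattern(geometry, 1000, seed=123)
    labels = assign_region(cells, geometry).labels
    area = geometry.region_area_fractions()
    observed = [np.sum(labels == r) for r in ("PM", "CM", "DM")]
    expected = [1000 * area[r] for r in ("PM", "CM", "DM")]
    assert sps.chisquare(observed, expected).pvalue > 0.01


def test_region_proportions_counting_and_weights(small_section):
    geometry, _, _ = small_section
    b1, b2 = geometry.region_bounds_um
    # 2 PM, 1 CM, 1 DM
    cells = CellPattern([0.1, b1 / 2, b1 + 1, b2 + 1], [1, 1, 1, 1])
    assignment = assign_region(cells, geometry)
    assert region_proportions(assignment) == \
        {"PM": 0.5, "CM": 0.25, "DM": 0.25}
    weighted = region_proportions(assignment,
                                  weights=np.array([1.0, 2.0, 3.0, 4.0]))
    assert weighted == {"PM": 0.3, "CM": 0.3, "DM": 0.4}
    assert sum(weighted.values()) == pytest.approx(1.0, abs=1e-12)


def test_all_cells_one_region(small_section):
    geometry, _, _ = small_section
    cells = CellPattern([1.0, 2.0, 3.0], [1, 1, 1])
    props = region_proportions(assign_region(cells, geometry))
    assert props == {"PM": 1.0, "CM": 0.0, "DM": 0.0}


def test_empty_assignment_is_an_error(small_section):
    geometry, _, _ = small_section
    from marrowmap.distances import RegionAssignment
    with pytest.raises(ValidationError):
        region_proportions(RegionAssignment(labels=np.array([])))
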