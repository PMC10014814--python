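"""Geometry primitives: generators, closure, membership, fragments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relbench.geometry import (
    Contour,
    DegenerateGeometryError,
    PolygonSpec,
    RadialContourSpec,
    RectangleSpec,
    distance_to_contour,
    extract_fragment,
    generate_amoeboid,
    generate_rectangle,
    generate_regular_polygon,
    point_in_region,
    points_in_region,
    similarity_fit_residual,
    turning_angle,
)
from relbench.render import rasterize_scene


# ---------------------------------------------------------------------------
# amoeboid generator
# ---------------------------------------------------------------------------


def test_zero_perturbation_amoeboid_is_a_circle():
    spec = RadialContourSpec(n_control=10, base_radius=1.0, perturbation_range=0.0, seed=0)
    c = generate_amoeboid(spec)
    radii = np.linalg.norm(c.vertices, axis=1)
    assert np.allclose(radii, 1.0, atol=1e-6)


@pytest.mark.parametrize("seed", [1, 7, 23])
@pytest.mark.parametrize("n_control", [10, 16])
def test_amoeboid_turning_angle_is_one_turn(seed, n_control):
    c = generate_amoeboid(RadialContourSpec(n_control=n_control, seed=seed))
    assert abs(abs(turning_angle(c)) - 360.0) < 1.0


def test_amoeboid_interpolates_control_points():
    """The periodic spline passes through all 16 control points."""
    c = generate_amoeboid(RadialContourSpec(n_control=16, seed=7))
    for p in c.control_points:
        assert distance_to_contour(p, c) < 1e-3


def test_amoeboid_deterministic():
    a = generate_amoeboid(RadialContourSpec(seed=42))
    b = generate_amoeboid(RadialContourSpec(seed=42))
    assert np.array_equal(a.vertices, b.vertices)


def test_amoeboid_simple_over_many_seeds():
    for seed in range(60):
        c = generate_amoeboid(RadialContourSpec(seed=seed))
        assert c.is_simple()


# ---------------------------------------------------------------------------
# polygons and rectangles
# ---------------------------------------------------------------------------


def test_square_polygon_regularity():
    c = generate_regular_polygon(PolygonSpec(4, 30.0, 0.0))
    sides = np.linalg.norm(np.diff(np.vstack([c.vertices, c.vertices[:1]]), axis=0), axis=1)
    assert np.allclose(sides, sides[0], atol=1e-6)
    # longest vertex-to-vertex distance equals the requested extent
    d = np.linalg.norm(c.vertices[:, None] - c.vertices[None], axis=2)
    assert abs(d.max() - 30.0) < 1e-9


def test_triangle_interior_angles():
    c = generate_regular_polygon(PolygonSpec(3, 30.0, 0.0))
    v = c.vertices
    for i in range(3):
        a, b, cc = v[i], v[(i + 1) % 3], v[(i + 2) % 3]
        u1, u2 = b - a, cc - a
        cosang = u1 @ u2 / (np.linalg.norm(u1) * np.linalg.norm(u2))
        assert abs(np.degrees(np.arccos(cosang)) - 60.0) < 1e-6


def test_polygon_extent_rejection():
    with pytest.raises(ValueError):
        generate_regular_polygon(PolygonSpec(5, 21.0, 0.0), admissible_extent=(22, 42))


@pytest.mark.parametrize("n", [3, 4, 5, 6, 8, 10])
def test_polygon_interior_angle_sum(n):
    c = generate_regular_polygon(PolygonSpec(n, 30.0, 15.0))
    # interior angle sum = (n-2)*180 exactly <=> exterior turning = 360
    assert abs(turning_angle(c) - 360.0) < 1e-9


def test_rectangle_aspect_measured():
    c = generate_rectangle(RectangleSpec(0.5, 40.0))
    x0, y0, x1, y1 = c.bbox()
    assert abs((y1 - y0) / (x1 - x0) - 0.5) < 1e-6


def test_rectangle_square_and_rejection():
    sq = generate_rectangle(RectangleSpec(1.0, 10.0))
    sides = np.linalg.norm(np.diff(np.vstack([sq.vertices, sq.vertices[:1]]), axis=0), axis=1)
    assert np.allclose(sides, sides[0])
    with pytest.raises(ValueError):
        RectangleSpec(0.05, 10.0)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------


def _nearest_polyline_distance(p, contour):
    """Independent point-to-polyline distance (exact per-segment projection)."""
    v = np.vstack([contour.vertices, contour.vertices[:1]])
    best = np.inf
    for a, b in zip(v[:-1], v[1:]):
        ab = b - a
        t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(a + t * ab - p)))
    return best


@pytest.mark.parametrize("fraction", [0.25, 0.37, 0.50])
def test_fragment_arc_length_ratio(fraction, rng):
    parent = generate_amoeboid(RadialContourSpec(seed=11))
    frag = extract_fragment(parent, fraction, rng.uniform())
    ratio = frag.arc_length() / parent.arc_length()
    assert abs(ratio - fraction) < 0.01


def test_fragment_endpoints_lie_on_parent(rng):
    parent = generate_amoeboid(RadialContourSpec(seed=13))
    for _ in range(5):
        frag = extract_fragment(parent, rng.uniform(0.25, 0.5), rng.uniform())
        assert not frag.closed
        for endpoint in (frag.vertices[0], frag.vertices[-1]):
            assert _nearest_polyline_distance(endpoint, parent) < 1e-6


def test_fragment_fraction_bounds():
    parent = generate_amoeboid(RadialContourSpec(seed=1))
    with pytest.raises(ValueError):
        extract_fragment(parent, 0.6, 0.0)
    with pytest.raises(ValueError):
        extract_fragment(parent, 0.1, 0.0)


def test_fragment_on_unit_circle_quarter():
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    circle = Contour(np.column_stack([np.cos(theta), np.sin(theta)]), closed=True)
    frag = extract_fragment(circle, 0.25, 0.0)
    assert abs(frag.arc_length() / circle.arc_length() - 0.25) < 0.01


# ---------------------------------------------------------------------------
# turning angle
# ---------------------------------------------------------------------------


def test_turning_angle_circle_polygon():
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    c = Contour(np.column_stack([np.cos(theta), np.sin(theta)]), closed=True)
    assert abs(turning_angle(c) - 360.0) < 0.1


def test_turning_angle_quarter_arc():
    theta = np.linspace(0, np.pi / 2, 256)
    c = Contour(np.column_stack([np.cos(theta), np.sin(theta)]), closed=False)
    assert abs(abs(turning_angle(c)) - 90.0) < 1.0


def test_turning_angle_orientation_sign():
    ccw = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float), closed=True)
    assert abs(abs(turning_angle(ccw)) - 360.0) < 1e-9


def test_turning_angle_degenerate_reversal():
    c = Contour(np.array([[0, 0], [1, 0], [0, 0.0000001], [0.5, 1]]), closed=False)
    # near-reversal is fine; exact reversal raises
    spike = Contour(np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]]), closed=False)
    with pytest.raises(DegenerateGeometryError):
        turning_angle(spike)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_turning_angle_of_random_convex_polygon_is_one_turn(seed):
    rng = np.random.default_rng(seed)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=rng.integers(3, 12)))
    if len(np.unique(np.round(angles, 6))) < 3:
        return
    pts = np.column_stack([np.cos(angles), np.sin(angles)])
    c = Contour(pts, closed=True)
    assert abs(abs(turning_angle(c)) - 360.0) < 1e-6


# ---------------------------------------------------------------------------
# point-in-region vs flood-fill oracle
# ---------------------------------------------------------------------------


def flood_fill_interior_mask(contour, frame_px=227):
    """Oracle: rasterize the closed contour, flood the exterior from a corner."""
    from skimage.segmentation import flood

    img = rasterize_scene([contour], frame_px=frame_px)
    ink = (img == 0).all(axis=2)
    exterior = flood(ink, (0, 0), connectivity=1)
    return ~(exterior | ink)


def _band_distance_mask(points, contour, band=1.0):
    return np.array([distance_to_contour(p, contour) > band for p in points])


@pytest.mark.parametrize("shape_seed", [3, 17])
def test_point_in_region_matches_flood_fill(shape_seed, rng):
    from relbench.datasets import canonical_amoeboid

    from relbench.render import rasterize_scene as _rast

    c = canonical_amoeboid(shape_seed).transformed(120.0, (113, 113))
    mask = flood_fill_interior_mask(c)
    ink = (_rast([c]) == 0).all(axis=2)
    pts = rng.uniform(1, 226, size=(1000, 2))
    # exclude a 1-px band around the ideal curve and stroke (boundary) pixels
    off_band = _band_distance_mask(pts, c, band=1.0)
    pts = pts[off_band]
    on_ink = np.array([ink[int(p[1]), int(p[0])] for p in pts])
    pts = pts[~on_ink]
    predicted = points_in_region(pts, c)
    oracle = np.array([mask[int(p[1]), int(p[0])] for p in pts])
    assert (predicted == oracle).mean() >= 0.999


def test_point_in_region_trivials():
    from relbench.datasets import canonical_amoeboid

    circle = generate_amoeboid(RadialContourSpec(perturbation_range=0.0, seed=0))
    assert point_in_region((0.0, 0.0), circle)
    assert not point_in_region((5.0, 5.0), circle)
    open_arc = extract_fragment(circle, 0.3, 0.0)
    with pytest.raises(ValueError):
        point_in_region((0, 0), open_arc)


# ---------------------------------------------------------------------------
# similarity fit
# ---------------------------------------------------------------------------


def test_similarity_fit_residual_same_vs_different():
    from relbench.datasets import canonical_amoeboid

    base = canonical_amoeboid(5)
    a = base.transformed(50.0, (60, 60))
    b = base.transformed(65.0, (150, 140))
    assert similarity_fit_residual(a, b) < 1e-9
    other = canonical_amoeboid(6).transformed(50.0, (60, 60))
    assert similarity_fit_residual(a, other) > 1.0
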