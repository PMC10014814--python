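"""2-D contour primitives shared by all three relation tasks.

Everything downstream — dataset composition, rendering, ground-truth
recomputation, observer simulation — is built on the :class:`Contour`:
an ordered chain of sub-pixel ``(x, y)`` vertices, open or closed.
Coordinates follow the raster convention: origin at the top-left,
``x`` rightward, ``y`` downward, pixel centers at ``integer + 0.5``.

Closed "amoeboid" contours are made by radially jittering control points
placed on a circle and interpolating with a periodic cubic spline; open
noise fragments are contiguous arcs cut from such parents.  Regular
polygons and axis-aligned rectangles cover the remaining stimulus
families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon as _ShPolygon


class GenerationError(RuntimeError):
    """A generator could not produce a valid contour within its attempt budget."""


class DegenerateGeometryError(ValueError):
    """The requested quantity is undefined for this vertex chain."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadialContourSpec:
    """Parameters of the radial-jitter + periodic-cubic-spline generator.

    ``base_radius`` is in whatever length unit the caller works in (canonical
    shapes use 1.0 and are scaled at placement time).  ``perturbation_range``
    is the half-width of the uniform radial jitter as a fraction of
    ``base_radius``: each control point sits at ``base_radius * (1 + u)`` with
    ``u ~ U(-p, p)``.
    """

    n_control: int = 10
    base_radius: float = 1.0
    perturbation_range: float = 0.3
    samples_per_segment: int = 12
    seed: int = 0
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if self.n_control < 3:
            raise ValueError("n_control must be >= 3")
        if not 0.0 <= self.perturbation_range < 1.0:
            raise ValueError("perturbation_range must be in [0, 1)")
        if self.samples_per_segment < 2:
            raise ValueError("samples_per_segment must be >= 2")


@dataclass(frozen=True)
class PolygonSpec:
    n_sides: int
    extent_px: float  # longest vertex-to-vertex distance
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sides < 3:
            raise ValueError("n_sides must be >= 3")
        if not 0.0 <= self.orientation_deg < 360.0:
            raise ValueError("orientation_deg must be in [0, 360)")


RECT_ASPECT_BOUNDS = (0.08, 1.0)


@dataclass(frozen=True)
class RectangleSpec:
    aspect: float  # minor / principal axis ratio
    extent: float  # principal-axis length, caller's units

    def __post_init__(self) -> None:
        lo, hi = RECT_ASPECT_BOUNDS
        if not lo <= self.aspect <= hi:
            raise ValueError(f"aspect must be in [{lo}, {hi}]")
        if self.extent <= 0:
            raise ValueError("extent must be positive")


# ---------------------------------------------------------------------------
# the geometry carrier
# ---------------------------------------------------------------------------


@dataclass
class Contour:
    """Ordered sub-pixel vertex chain; the universal geometry carrier."""

    vertices: np.ndarray  # (N, 2) float
    closed: bool
    parent_id: Optional[str] = None
    shape_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        n = len(self.vertices)
        if self.closed and n < 3:
            raise ValueError("a closed contour needs at least 3 vertices")
        if n >= 2:
            d = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
            if np.any(d == 0.0):
                raise ValueError("consecutive vertices must be distinct")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """(M, 2, 2) array of segments; includes the closing edge if closed."""
        v = self.vertices
        if self.closed:
            nxt = np.roll(v, -1, axis=0)
        else:
            nxt = v[1:]
            v = v[:-1]
        return np.stack([v, nxt], axis=1)

    def arc_length(self) -> float:
        seg = self.edges()
        return float(np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1).sum())

    def centroid(self) -> np.ndarray:
        """Mean of the vertices (not the area centroid)."""
        return self.vertices.mean(axis=0)

    def bbox(self) -> tuple[float, float, float, float]:
        x0, y0 = self.vertices.min(axis=0)
        x1, y1 = self.vertices.max(axis=0)
        return float(x0), float(y0), float(x1), float(y1)

    def bbox_extent(self) -> float:
        """Longest horizontal-or-vertical extent (max bounding-box side)."""
        x0, y0, x1, y1 = self.bbox()
        return max(x1 - x0, y1 - y0)

    def transformed(self, scale: float = 1.0, offset=(0.0, 0.0)) -> "Contour":
        return replace(
            self, vertices=self.vertices * scale + np.asarray(offset, dtype=float)
        )

    def is_simple(self) -> bool:
        if not self.closed:
            return True
        return _ShPolygon(self.vertices).is_valid

    def to_dict(self) -> dict:
        return {
            "vertices": np.round(self.vertices, 4).tolist(),
            "closed": self.closed,
            "parent_id": self.parent_id,
            "shape_id": self.shape_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Contour":
        return cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            closed=bool(d["closed"]),
            parent_id=d.get("parent_id"),
            shape_id=d.get("shape_id"),
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _radial_spline_loop(radii: np.ndarray, samples_per_segment: int) -> np.ndarray:
    """Periodic cubic spline of radius over angle, sampled uniformly in angle.

    Interpolating the *radius* (rather than Cartesian points) matches the
    generative idea — control points move only toward or away from the
    center — and makes the zero-perturbation limit an exact circle.  The
    resulting contour is star-shaped about the origin, hence always simple.
    """
    n = len(radii)
    knots = np.arange(n + 1, dtype=float)
    r = np.concatenate([radii, radii[:1]])  # periodic closure
    spline = CubicSpline(knots, r, bc_type="periodic")
    t = np.arange(n * samples_per_segment, dtype=float) / samples_per_segment
    theta = 2.0 * np.pi * t / n
    rr = spline(t)
    return np.column_stack([rr * np.cos(theta), rr * np.sin(theta)])


def generate_amoeboid(spec: RadialContourSpec, shape_id: Optional[str] = None) -> Contour:
    """Smooth closed contour from radially jittered control points on a circle.

    Control points sit at uniform angular spacing; radii are drawn uniformly
    from ``base_radius * (1 ± perturbation_range)``.  A periodic cubic spline
    interpolates the control-point radii exactly.  Because the contour is a
    radial function of angle it cannot self-intersect as long as the
    interpolated radius stays positive; draws violating that (possible only
    at extreme perturbations, via spline overshoot) are resampled.
    """
    rng = np.random.default_rng(spec.seed)
    angles = 2.0 * np.pi * np.arange(spec.n_control) / spec.n_control
    for _ in range(spec.max_attempts):
        radii = spec.base_radius * (
            1.0 + rng.uniform(-spec.perturbation_range, spec.perturbation_range,
                              size=spec.n_control)
        )
        verts = _radial_spline_loop(radii, spec.samples_per_segment)
        if np.linalg.norm(verts, axis=1).min() <= 0.0:
            continue
        contour = Contour(verts, closed=True, shape_id=shape_id)
        contour.control_points = np.column_stack(
            [radii * np.cos(angles), radii * np.sin(angles)]
        )  # kept for interpolation audits
        return contour
    raise GenerationError(
        f"no positive-radius contour after {spec.max_attempts} attempts (spec={spec})"
    )


def generate_regular_polygon(
    spec: PolygonSpec,
    admissible_extent: Optional[tuple[float, float]] = None,
    shape_id: Optional[str] = None,
) -> Contour:
    """Closed regular (equilateral, equiangular) polygon.

    ``extent_px`` is the longest vertex-to-vertex distance; for an n-gon on a
    circumcircle of radius R that chord is ``2 R sin(floor(n/2) * pi / n)``.
    """
    if admissible_extent is not None:
        lo, hi = admissible_extent
        if not lo <= spec.extent_px <= hi:
            raise ValueError(
                f"extent {spec.extent_px} outside admissible range [{lo}, {hi}]"
            )
    n = spec.n_sides
    longest_chord = 2.0 * np.sin(np.floor(n / 2) * np.pi / n)
    radius = spec.extent_px / longest_chord
    theta = 2.0 * np.pi * np.arange(n) / n + np.deg2rad(spec.orientation_deg)
    verts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return Contour(verts, closed=True, shape_id=shape_id)


def generate_rectangle(spec: RectangleSpec, shape_id: Optional[str] = None) -> Contour:
    """Axis-aligned rectangle with principal axis ``extent`` and the given aspect."""
    w = spec.extent
    h = spec.aspect * spec.extent
    verts = 0.5 * np.array([[-w, -h], [w, -h], [w, h], [-w, h]])
    return Contour(verts, closed=True, shape_id=shape_id)


FRAGMENT_FRACTION_BOUNDS = (0.25, 0.50)


def extract_fragment(
    parent: Contour,
    fraction: float,
    start_phase: float,
    fragment_id: Optional[str] = None,
) -> Contour:
    """Cut a contiguous open arc covering ``fraction`` of a closed parent's length.

    ``start_phase`` in [0, 1) picks where along the perimeter the arc starts.
    """
    if not parent.closed:
        raise ValueError("fragments are cut from closed contours")
    lo, hi = FRAGMENT_FRACTION_BOUNDS
    if not lo <= fraction <= hi:
        raise ValueError(f"fraction must be in [{lo}, {hi}]")

    v = np.vstack([parent.vertices, parent.vertices[:1]])
    seg_len = np.linalg.norm(np.diff(v, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    def point_at(s: float) -> np.ndarray:
        s = s % total
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg_len) - 1)
        f = (s - cum[i]) / seg_len[i]
        return v[i] + f * (v[i + 1] - v[i])

    s0 = (start_phase % 1.0) * total
    s1 = s0 + fraction * total
    # interior vertex arc positions strictly inside (s0, s1), unwrapped
    interior_s = [
        s for s in cum[:-1] + np.where(cum[:-1] < s0, total, 0.0) if s0 < s < s1
    ]
    interior_s.sort()
    pts = [point_at(s0)] + [point_at(s) for s in interior_s] + [point_at(s1)]
    pts = np.asarray(pts)
    # drop numerically duplicate neighbors (arc endpoint can land on a vertex)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    return Contour(
        pts, closed=False, parent_id=parent.shape_id, shape_id=fragment_id
    )


# ---------------------------------------------------------------------------
# predicates and measurements
# ---------------------------------------------------------------------------


def turning_angle(c: Contour) -> float:
    """Total signed exterior angle of the vertex chain, in degrees.

    For a simple closed contour this integrates to ±360°; for an open arc it
    approximates the tangent-direction change along the arc.  The closing edge
    is included iff the contour is closed.
    """
    if c.n_vertices < 3:
        raise DegenerateGeometryError("need at least 3 vertices")
    v = c.vertices
    if c.closed:
        d = np.roll(v, -1, axis=0) - v  # edge i: v[i] -> v[i+1]
        pairs = zip(d, np.roll(d, -1, axis=0))
    else:
        d = np.diff(v, axis=0)
        pairs = zip(d[:-1], d[1:])
    total = 0.0
    for a, b in pairs:
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0.0 or nb == 0.0:
            raise DegenerateGeometryError("zero-length edge")
        cross = a[0] * b[1] - a[1] * b[0]
        dot = float(a @ b)
        if cross == 0.0 and dot < 0.0:
            raise DegenerateGeometryError("180-degree reversal: angle sign undefined")
        total += np.arctan2(cross, dot)
    return float(np.degrees(total))


def point_in_region(p, c: Contour) -> bool:
    """Ray-crossing parity test for a point against a closed contour."""
    if not c.closed:
        raise ValueError("point_in_region requires a closed contour")
    return bool(points_in_region(np.asarray(p, dtype=float)[None, :], c)[0])


def points_in_region(points: np.ndarray, c: Contour) -> np.ndarray:
    """Vectorized ray-crossing parity test; ``points`` is (N, 2)."""
    if not c.closed:
        raise ValueError("points_in_region requires a closed contour")
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0][:, None], pts[:, 1][:, None]
    v1 = c.vertices
    v2 = np.roll(v1, -1, axis=0)
    x1, y1 = v1[:, 0][None, :], v1[:, 1][None, :]
    x2, y2 = v2[:, 0][None, :], v2[:, 1][None, :]
    straddles = (y1 > y) != (y2 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at_y = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
    crossings = straddles & (x < x_at_y)
    return crossings.sum(axis=1) % 2 == 1


def distance_to_contour(p, c: Contour) -> float:
    """Minimum Euclidean distance from a point to the contour polyline."""
    seg = c.edges()
    a, b = seg[:, 0], seg[:, 1]
    p = np.asarray(p, dtype=float)
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    t = np.clip(((p - a) * ab).sum(axis=1) / np.where(denom == 0, 1, denom), 0, 1)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(proj - p, axis=1).min())


def similarity_fit_residual(a: Contour, b: Contour) -> float:
    """RMS residual of the best scale + translation map from ``a`` onto ``b``.

    Vertices are taken in corresponding order (the generators emit a canonical
    vertex ordering, so two placements of the same library shape correspond
    index-by-index).  Rotation is deliberately not fitted: "Same" pairs differ
    by translation and uniform scale only.
    """
    va, vb = a.vertices, b.vertices
    if va.shape != vb.shape:
        return float("inf")
    ca, cb = va.mean(axis=0), vb.mean(axis=0)
    da, db = va - ca, vb - cb
    denom = (da * da).sum()
    s = (da * db).sum() / denom if denom > 0 else 0.0
    resid = s * da - db
    return float(np.sqrt((resid**2).sum(axis=1).mean()))


def segments_intersect(p1, p2, q1, q2) -> bool:
    """Proper or touching intersection of segments p1p2 and q1q2."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12
            and min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12
        )

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if o1 != o2 and o3 != o4:
        return True
    if o1 == 0 and on_seg(p1, p2, q1):
        return True
    if o2 == 0 and on_seg(p1, p2, q2):
        return True
    if o3 == 0 and on_seg(q1, q2, p1):
        return True
    if o4 == 0 and on_seg(q1, q2, p2):
        return True
    return False


def contours_disjoint(a: Contour, b: Contour, min_gap: float = 0.0) -> bool:
    """True iff the two contours neither intersect nor contain one another.

    With ``min_gap`` > 0 the shapely distance between the (closed) outlines
    must exceed the gap.
    """
    pa = _ShPolygon(a.vertices) if a.closed else None
    pb = _ShPolygon(b.vertices) if b.closed else None
    if pa is not None and pb is not None:
        if min_gap > 0:
            return pa.distance(pb) > min_gap and not (
                pa.contains(pb) or pb.contains(pa)
            )
        return not pa.intersects(pb)
    # open-contour fallback: brute-force edge test
    for s1 in a.edges():
        for s2 in b.edges():
            if segments_intersect(s1[0], s1[1], s2[0], s2[1]):
                return False
    return True
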