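"""Arena geometry for the heated center-finding setup.

Four enclosure shapes of approximately equal floor area (709 cm^2, +/- 3%)
are used: a circle (d = 30 cm), a square (edge 27 cm), an equilateral
triangle (edge 40 cm) and an asymmetric quadrilateral (edges 37, 24, 23,
26 cm with interior angles 67, 80, 100, 113 degrees). The refuge ("cool
spot") is a 60 mm diameter disc at the geometric center of the symmetric
shapes and at the area centroid of the quadrilateral.

Canonical frame: centimetres, cool spot at the origin, x right, y up.
Polygon boundaries are stored as counter-clockwise vertex lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "ShapeSpec",
    "Arena",
    "CalibrationTransform",
    "ArenaConstructionError",
    "CalibrationError",
    "SHAPE_SPECS",
    "build_arena",
    "arena_area",
    "polygon_area",
    "polygon_centroid",
    "distance_to_perimeter",
    "contains",
    "centroid",
    "canonical_landmarks",
    "calibrate_from_landmarks",
]

DESIGN_AREA_CM2 = 709.0
AREA_TOLERANCE = 0.03
COOL_SPOT_RADIUS_CM = 3.0  # 60 mm water-cooling block
CLOSURE_TOLERANCE_CM = 1.0  # printed dimensions are rounded to cm / degree


class ArenaConstructionError(ValueError):
    """Raised when a shape specification cannot produce a valid arena."""


class CalibrationError(ValueError):
    """Raised when landmark calibration fails or is degenerate."""


@dataclass(frozen=True)
class ShapeSpec:
    """Printed dimensions of one arena shape.

    ``dimensions`` holds the characteristic lengths in cm (diameter for the
    circle, edge(s) otherwise); ``angles_deg`` the interior angles for the
    quadrilateral, in the order they are visited when walking the edges.
    """

    shape_kind: str
    dimensions: tuple[float, ...]
    angles_deg: tuple[float, ...] = ()
    design_area: float = DESIGN_AREA_CM2
    area_tolerance: float = AREA_TOLERANCE

    def __post_init__(self) -> None:
        if self.shape_kind not in ("circle", "square", "triangle", "quadrilateral"):
            raise ArenaConstructionError(f"unknown shape kind {self.shape_kind!r}")
        if any(d <= 0 for d in self.dimensions):
            raise ArenaConstructionError("all edge lengths must be strictly positive")
        if self.shape_kind == "quadrilateral":
            if len(self.dimensions) != 4 or len(self.angles_deg) != 4:
                raise ArenaConstructionError(
                    "quadrilateral needs 4 edges and 4 interior angles"
                )
            if abs(sum(self.angles_deg) - 360.0) > 1e-9:
                raise ArenaConstructionError("interior angles must sum to 360 degrees")


#: The four published arena specifications.
SHAPE_SPECS: dict[str, ShapeSpec] = {
    "circle": ShapeSpec("circle", (30.0,)),
    "square": ShapeSpec("square", (27.0,)),
    "triangle": ShapeSpec("triangle", (40.0,)),
    "quadrilateral": ShapeSpec(
        "quadrilateral", (37.0, 24.0, 23.0, 26.0), (67.0, 80.0, 100.0, 113.0)
    ),
}


@dataclass(frozen=True)
class Arena:
    """A canonical arena: boundary + cool spot, in cm, cool spot at (0, 0).

    ``radius`` is set for the circle only; ``vertices`` (counter-clockwise,
    shape (n, 2)) for the polygons only.
    """

    shape_kind: str
    cool_spot_radius: float = COOL_SPOT_RADIUS_CM
    radius: float | None = None
    vertices: np.ndarray | None = None
    cool_spot_center: tuple[float, float] = (0.0, 0.0)
    closure_residual: float = 0.0

    def __post_init__(self) -> None:
        if (self.radius is None) == (self.vertices is None):
            raise ArenaConstructionError("exactly one of radius/vertices must be set")

    @property
    def is_circle(self) -> bool:
        return self.radius is not None

    def as_shapely(self) -> Polygon:
        """Shapely polygon of the boundary (circle approximated finely)."""
        if self.is_circle:
            return Point(0.0, 0.0).buffer(self.radius, quad_segs=256)
        return Polygon(self.vertices)


def polygon_area(vertices: np.ndarray) -> float:
    """Signed-magnitude shoelace area of a closed polygon (vertices not repeated)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid via the shoelace-weighted formula."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        # degenerate polygon: fall back to the vertex average
        return v.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _walk_quadrilateral(spec: ShapeSpec) -> tuple[np.ndarray, float]:
    """Construct the quadrilateral by walking printed edges and angles.

    Starts at (0, 0) heading along +x; at each subsequent vertex turns left
    by the exterior angle (180 - interior). The first printed angle sits at
    the starting vertex (between the last and first edge) and is therefore
    not used while walking. Returns (vertices, closure residual).
    """
    edges = spec.dimensions
    interior = spec.angles_deg
    pts = [np.zeros(2)]
    heading = 0.0
    for i, edge in enumerate(edges):
        pts.append(pts[-1] + edge * np.array([math.cos(heading), math.sin(heading)]))
        if i + 1 < len(edges):
            heading += math.radians(180.0 - interior[i + 1])
    closure = float(np.linalg.norm(pts[-1] - pts[0]))
    return np.array(pts[:-1]), closure


def build_arena(spec: ShapeSpec) -> Arena:
    """Construct the canonical arena for ``spec``.

    The result is translated so the cool spot (center of symmetry, or the
    area centroid for the quadrilateral) sits at the origin. Raises
    :class:`ArenaConstructionError` if the walked polygon fails to close
    within tolerance or the area falls outside the design band.
    """
    kind = spec.shape_kind
    closure = 0.0
    if kind == "circle":
        arena = Arena("circle", radius=spec.dimensions[0] / 2.0)
    elif kind == "square":
        h = spec.dimensions[0] / 2.0
        verts = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
        arena = Arena("square", vertices=verts)
    elif kind == "triangle":
        # equilateral, one vertex up, centroid at origin
        rc = spec.dimensions[0] / math.sqrt(3.0)  # circumradius
        ang = np.radians([90.0, 210.0, 330.0])
        verts = rc * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        arena = Arena("triangle", vertices=_ensure_ccw(verts))
    else:
        verts, closure = _walk_quadrilateral(spec)
        if closure > CLOSURE_TOLERANCE_CM:
            raise ArenaConstructionError(
                f"quadrilateral fails to close: residual {closure:.3f} cm"
            )
        verts = verts - polygon_centroid(verts)
        arena = Arena("quadrilateral", vertices=_ensure_ccw(verts), closure_residual=closure)

    area = arena_area(arena)
    lo = spec.design_area * (1.0 - spec.area_tolerance)
    hi = spec.design_area * (1.0 + spec.area_tolerance)
    if not (lo <= area <= hi):
        raise ArenaConstructionError(
            f"{kind} area {area:.2f} cm^2 outside {spec.design_area} +/- "
            f"{100 * spec.area_tolerance:.0f}%"
        )
    if distance_to_perimeter(arena, (0.0, 0.0)) <= arena.cool_spot_radius:
        raise ArenaConstructionError("cool spot does not lie strictly inside the boundary")
    return arena


def _ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    return v if signed > 0 else v[::-1].copy()


def arena_area(arena: Arena) -> float:
    """Floor area in cm^2 (pi r^2, or the shoelace sum for polygons)."""
    if arena.is_circle:
        return math.pi * arena.radius**2
    return polygon_area(arena.vertices)


def _segment_distances(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Min distance from each point to the closed polyline through vertices.

    Vectorised point-to-segment projection over all edges at once.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))  # (m, 2)
    a = vertices  # (n, 2)
    b = np.roll(vertices, -1, axis=0)
    ab = b - a  # (n, 2)
    ab2 = np.maximum((ab**2).sum(axis=1), 1e-300)
    ap = p[:, None, :] - a[None, :, :]  # (m, n, 2)
    t = np.clip((ap * ab[None]).sum(axis=2) / ab2[None], 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(p[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def distance_to_perimeter(arena: Arena, p) -> float | np.ndarray:
    """Minimum Euclidean distance (cm) from point(s) ``p`` to the boundary.

    The magnitude is returned for interior and exterior points alike; it is
    exactly 0 on the boundary. Accepts a single (x, y) pair or an (m, 2)
    array, returning a scalar or a vector accordingly.
    """
    arr = np.asarray(p, dtype=float)
    scalar = arr.ndim == 1
    pts = np.atleast_2d(arr)
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    if arena.is_circle:
        d = np.abs(arena.radius - np.linalg.norm(pts, axis=1))
    else:
        d = _segment_distances(pts, arena.vertices)
    return float(d[0]) if scalar else d


def contains(arena: Arena, p) -> bool | np.ndarray:
    """Closed containment test: boundary points count as inside."""
    arr = np.asarray(p, dtype=float)
    scalar = arr.ndim == 1
    pts = np.atleast_2d(arr)
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    if arena.is_circle:
        inside = np.linalg.norm(pts, axis=1) <= arena.radius + 1e-12
    else:
        # winding via cross products; arenas are convex CCW polygons
        a = arena.vertices
        b = np.roll(a, -1, axis=0)
        ab = b - a
        ap = pts[:, None, :] - a[None, :, :]
        cross = ab[None, :, 0] * ap[..., 1] - ab[None, :, 1] * ap[..., 0]
        inside = (cross >= -1e-9).all(axis=1)
    return bool(inside[0]) if scalar else inside


def centroid(arena: Arena) -> np.ndarray:
    """Center of symmetry (circle/square/triangle) or the area centroid."""
    if arena.is_circle:
        return np.zeros(2)
    if arena.shape_kind in ("square", "triangle"):
        return np.asarray(arena.vertices).mean(axis=0)
    return polygon_centroid(arena.vertices)


def canonical_landmarks(arena: Arena) -> np.ndarray:
    """The four tracked reference points, in canonical cm coordinates.

    Polygon corners for the polygonal arenas (the triangle contributes its
    three corners plus the midpoint of its base wall so four points exist);
    for the circle, the four ends of two perpendicular diameters.
    """
    if arena.is_circle:
        r = arena.radius
        return np.array([[r, 0.0], [0.0, r], [-r, 0.0], [0.0, -r]])
    v = np.asarray(arena.vertices)
    if len(v) == 4:
        return v.copy()
    if len(v) == 3:
        mid = (v[0] + v[1]) / 2.0
        return np.vstack([v, mid])
    raise ArenaConstructionError(f"unsupported landmark layout for {arena.shape_kind}")


@dataclass(frozen=True)
class CalibrationTransform:
    """Similarity transform (pixels -> canonical cm frame).

    ``scale`` is cm per pixel; mapping is ``scale * R(rotation) @ p + translation``.
    """

    scale: float
    rotation: float
    translation: np.ndarray
    rms_residual: float

    def apply(self, points_px) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        out = self.scale * pts @ rot.T + self.translation
        return out if np.asarray(points_px).ndim > 1 else out[0]

    def invert(self) -> "CalibrationTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        rot = np.array([[c, -s], [s, c]])
        inv_t = -inv_scale * rot @ self.translation
        return CalibrationTransform(inv_scale, -self.rotation, inv_t, self.rms_residual)


def _fit_similarity(src: np.ndarray, dst: np.ndarray) -> CalibrationTransform:
    """Least-squares proper similarity mapping src onto dst.

    Solved in closed form as a complex linear regression dst = a*src + t.
    """
    z = src[:, 0] + 1j * src[:, 1]
    w = dst[:, 0] + 1j * dst[:, 1]
    zc = z - z.mean()
    wc = w - w.mean()
    denom = (zc.conj() * zc).sum().real
    if denom < 1e-12:
        raise CalibrationError("degenerate landmarks: all points coincide")
    a = (zc.conj() * wc).sum() / denom
    t = w.mean() - a * z.mean()
    fitted = a * z + t
    rms = float(np.sqrt(np.mean(np.abs(w - fitted) ** 2)))
    return CalibrationTransform(
        scale=abs(a),
        rotation=float(np.angle(a)),
        translation=np.array([t.real, t.imag]),
        rms_residual=rms,
    )


def calibrate_from_landmarks(
    tracked_px, arena: Arena, max_rms_cm: float = 1.0
) -> CalibrationTransform:
    """Fit the pixel -> cm similarity transform from 4 tracked landmarks.

    The correspondence between tracked points and canonical landmarks is
    unknown (trackers label corners arbitrarily), so all cyclic orders in
    both orientations are tried and the fit with minimum RMS residual kept.

    Raises :class:`CalibrationError` on duplicated/collinear landmarks or
    when the best residual exceeds ``max_rms_cm``.
    """
    px = np.asarray(tracked_px, dtype=float)
    if px.shape != (4, 2):
        raise CalibrationError("exactly 4 landmark points are required")
    if not np.isfinite(px).all():
        raise CalibrationError("landmarks must be finite")
    # duplicates
    for i in range(4):
        for j in range(i + 1, 4):
            if np.linalg.norm(px[i] - px[j]) < 1e-9:
                raise CalibrationError("degenerate landmarks: duplicated point")
    # collinearity (rank of the centered coordinates)
    centered = px - px.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-9 * np.abs(centered).max():
        raise CalibrationError("degenerate landmarks: collinear points")

    canon = canonical_landmarks(arena)
    best: CalibrationTransform | None = None
    for orientation in (px, px[::-1]):
        for shift in range(4):
            src = np.roll(orientation, shift, axis=0)
            cand = _fit_similarity(src, canon)
            if best is None or cand.rms_residual < best.rms_residual:
                best = cand
    assert best is not None
    if best.rms_residual > max_rms_cm:
        raise CalibrationError(
            f"calibration residual {best.rms_residual:.3f} cm exceeds {max_rms_cm} cm"
        )
    return best
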