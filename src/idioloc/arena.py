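"""Arena geometry: bounded 2D environments for localization experiments.

An :class:`Arena` is a traversable planar region bounded by a simple closed
outer curve, optionally containing zero-width interior barriers (open
polylines the agent cannot cross) and voids (closed holes excluded from the
traversable space).  Curved boundaries (circle, egg) are discretized to
fine polygons so that a single polygon code path serves all geometry
queries.  Coordinates are continuous centimetres in an arena-centred frame;
angles are radians internally.

The module answers three kinds of questions:

* containment — does a (possibly elliptic) agent body placed at a pose lie
  wholly inside the traversable space?
* crossing — does a movement segment cross any boundary (outer, barrier or
  void)?  This is the predicate the particle filter culls on.
* symmetry — how rotationally asymmetric is the traversable region, and
  what is its n-fold rotational symmetry order?  Arenas with 1-fold
  rotational symmetry (no non-trivial rotation maps them onto themselves)
  are the ones in which a disoriented agent can localize from self-motion
  cues alone.

Construction-time operations (areas, symmetric differences, erosions) use
shapely; the per-step queries used inside simulation loops are vectorized
numpy so that thousands of particles can be tested per time step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Optional, Sequence

import numpy as np
import shapely
import shapely.affinity
from matplotlib.path import Path as MplPath
from shapely.geometry import LineString, MultiLineString, Polygon

__all__ = [
    "Arena",
    "BodyShape",
    "AsymmetryProfile",
    "FastGeometry",
    "SYMMETRY_INF",
    "make_standard_arena",
    "contains",
    "segment_crosses",
    "rotational_asymmetry",
    "mean_rotational_asymmetry",
    "symmetry_order",
    "expand_arena",
    "save_arena",
    "load_arena",
    "STANDARD_ARENA_NAMES",
]

# Sentinel symmetry order for rotationally invariant regions (circle).
SYMMETRY_INF = math.inf

# Canonical circular arena: 76 cm diameter (the standard rodent open field
# used throughout; doubling the scale gives the 152 cm variant).
CIRCLE_DIAMETER = 76.0
_CANONICAL_AREA = math.pi * (CIRCLE_DIAMETER / 2.0) ** 2

# Discretization of curved boundaries; 360-gon keeps the chord error of a
# 38 cm radius circle under 0.015 mm (tolerance target 0.1 mm).
_CURVE_N = 360


@dataclass(frozen=True)
class BodyShape:
    """Agent body outline: an ellipse with semi-axes (a, b) in cm.

    ``(0, 0)`` is a point body.  ``a`` is aligned with the heading.
    """

    semi_axes: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        a, b = self.semi_axes
        if not (a >= b >= 0.0):
            raise ValueError(f"semi_axes must satisfy a >= b >= 0, got {self.semi_axes}")

    @property
    def is_point(self) -> bool:
        return self.semi_axes[0] == 0.0

    def perimeter_points(self, center, theta, n: int = 72) -> np.ndarray:
        """Sample ``n`` points on the body perimeter at pose (center, theta).

        Vectorized over poses: ``center`` may be (2,) or (P, 2) and ``theta``
        scalar or (P,); returns (n, 2) or (P, n, 2).
        """
        a, b = self.semi_axes
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        ex, ey = a * np.cos(t), b * np.sin(t)  # body frame
        center = np.asarray(center, dtype=float)
        theta = np.asarray(theta, dtype=float)
        c, s = np.cos(theta), np.sin(theta)
        if center.ndim == 1:
            x = center[0] + c * ex - s * ey
            y = center[1] + s * ex + c * ey
            return np.stack([x, y], axis=-1)
        x = center[:, 0, None] + c[:, None] * ex[None, :] - s[:, None] * ey[None, :]
        y = center[:, 1, None] + s[:, None] * ex[None, :] + c[:, None] * ey[None, :]
        return np.stack([x, y], axis=-1)


POINT_BODY = BodyShape()


@dataclass
class AsymmetryProfile:
    """Sampled rotational asymmetry function A(phi) of a traversable region.

    ``A(phi)`` is the area of the symmetric difference between the region
    and its rotation by ``phi`` about the region centroid, normalized by
    twice the region area; 0 means the rotation maps the region onto
    itself, values approach 1 for disjoint overlap.
    """

    angles_deg: np.ndarray
    values: np.ndarray
    mean_asymmetry: float
    symmetry_order: float  # n of n-RS; SYMMETRY_INF for circles


class FastGeometry:
    """Vectorized numpy geometry queries against a fixed arena.

    Precomputes the boundary edge set (outer ring, void rings, barrier
    segments) and matplotlib containment paths.  These are the hot-loop
    predicates used by the trajectory generator and the particle filter.
    """

    def __init__(self, outer: np.ndarray, voids: Sequence[np.ndarray],
                 barriers: Sequence[np.ndarray]):
        self.outer_path = MplPath(outer)
        self.void_paths = [MplPath(v) for v in voids]
        edges = [_ring_edges(outer)]
        edges += [_ring_edges(v) for v in voids]
        edges += [_polyline_edges(b) for b in barriers]
        self.edges = np.concatenate(edges, axis=0)  # (M, 2, 2)
        self._ea = self.edges[:, 0, :]
        self._eb = self.edges[:, 1, :]
        self._ed = self._eb - self._ea
        lines = [LineString(outer[list(range(len(outer))) + [0]])]
        lines += [LineString(v[list(range(len(v))) + [0]]) for v in voids]
        lines += [LineString(b) for b in barriers]
        self.boundary_lines = MultiLineString(lines)
        # convex outer boundary without barriers/voids: a segment between
        # two interior points can never cross the boundary, so crossing
        # reduces to endpoint containment
        poly = Polygon(outer)
        self._convex_simple = (not voids and not barriers
                               and poly.convex_hull.area <= poly.area * (1 + 1e-9))
        self._dist_grid = None  # lazy coarse distance field (prefilter)

    def contains_points(self, pts: np.ndarray) -> np.ndarray:
        """True where points lie in the traversable space (voids excluded)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inside = self.outer_path.contains_points(pts)
        for vp in self.void_paths:
            inside &= ~vp.contains_points(pts)
        return inside

    def segments_cross(self, p0: np.ndarray, p1: np.ndarray,
                       chunk: int = 2_000_000,
                       assume_inside: bool = False) -> np.ndarray:
        """True where the segment p0->p1 crosses any boundary edge.

        Endpoints outside the traversable space also count as crossing;
        ``assume_inside`` skips the start-point containment test (safe when
        the caller maintains the inside invariant, as the filter does).
        """
        p0 = np.atleast_2d(np.asarray(p0, dtype=float))
        p1 = np.atleast_2d(np.asarray(p1, dtype=float))
        out = ~self.contains_points(p1)
        if not assume_inside:
            out |= ~self.contains_points(p0)
        if self._convex_simple:
            return out
        m = len(self._ea)
        n = len(p0)
        if m <= 32:
            out |= self._proper_intersections_small(p0, p1)
            return out
        # coarse distance-field prefilter: a segment shorter than a safe
        # lower bound on the start point's boundary distance cannot cross
        reach = np.hypot(p1[:, 0] - p0[:, 0], p1[:, 1] - p0[:, 1])
        cand = np.flatnonzero(reach >= self._safe_boundary_distance(p0))
        step = max(1, chunk // m)
        for lo in range(0, len(cand), step):
            sel = cand[lo:lo + step]
            out[sel] |= self._proper_intersections(p0[sel], p1[sel])
        return out

    _DIST_GRID_H = 3.0  # cm

    def _safe_boundary_distance(self, pts: np.ndarray) -> np.ndarray:
        """Conservative lower bound on distance to the nearest boundary,
        from a precomputed coarse distance field."""
        if self._dist_grid is None:
            h = self._DIST_GRID_H
            xs, ys = self.edges[:, :, 0], self.edges[:, :, 1]
            x0, x1 = xs.min() - 2 * h, xs.max() + 2 * h
            y0, y1 = ys.min() - 2 * h, ys.max() + 2 * h
            gx = np.arange(x0, x1 + h, h)
            gy = np.arange(y0, y1 + h, h)
            xx, yy = np.meshgrid(gx, gy)
            nodes = np.stack([xx.ravel(), yy.ravel()], axis=1)
            d = shapely.distance(shapely.points(nodes), self.boundary_lines)
            # subtract the cell diagonal so the bound holds anywhere in-cell
            grid = (d.reshape(xx.shape) - h * math.sqrt(2.0)).clip(min=0.0)
            self._dist_grid = (x0, y0, h, grid)
        x0, y0, h, grid = self._dist_grid
        ix = np.clip(((pts[:, 0] - x0) / h).astype(int), 0, grid.shape[1] - 1)
        iy = np.clip(((pts[:, 1] - y0) / h).astype(int), 0, grid.shape[0] - 1)
        return grid[iy, ix]

    def _proper_intersections_small(self, p0, p1):
        # per-edge loop: cheaper than full broadcasting for few edges
        x0, y0 = p0[:, 0], p0[:, 1]
        dx, dy = p1[:, 0] - x0, p1[:, 1] - y0
        out = np.zeros(len(p0), dtype=bool)
        for (ax, ay), (ex_, ey_) in zip(self._ea, self._ed):
            rx, ry = x0 - ax, y0 - ay
            c1 = ex_ * ry - ey_ * rx
            c2 = ex_ * (ry + dy) - ey_ * (rx + dx)
            straddle = c1 * c2 < 0.0
            if not straddle.any():
                continue
            c3 = dy * rx - dx * ry
            c4 = dx * (ay + ey_ - y0) - dy * (ax + ex_ - x0)
            out |= straddle & (c3 * c4 < 0.0)
        return out

    def _proper_intersections(self, p0, p1):
        a = self._ea[None, :, :]   # (1, M, 2)
        d_e = self._ed[None, :, :]
        q0 = p0[:, None, :]        # (N, 1, 2)
        d_s = (p1 - p0)[:, None, :]
        r0 = q0 - a
        r1 = r0 + d_s
        c1 = d_e[..., 0] * r0[..., 1] - d_e[..., 1] * r0[..., 0]
        c2 = d_e[..., 0] * r1[..., 1] - d_e[..., 1] * r1[..., 0]
        s0 = a - q0
        s1 = s0 + d_e
        c3 = d_s[..., 0] * s0[..., 1] - d_s[..., 1] * s0[..., 0]
        c4 = d_s[..., 0] * s1[..., 1] - d_s[..., 1] * s1[..., 0]
        cross = (c1 * c2 < 0.0) & (c3 * c4 < 0.0)
        return cross.any(axis=1)

    def distance_to_boundary(self, pts: np.ndarray) -> np.ndarray:
        """Euclidean distance from points to the nearest boundary line."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        geoms = shapely.points(pts)
        return shapely.distance(geoms, self.boundary_lines)


def _ring_edges(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    nxt = np.roll(v, -1, axis=0)
    return np.stack([v, nxt], axis=1)


def _polyline_edges(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    return np.stack([v[:-1], v[1:]], axis=1)


@dataclass
class Arena:
    """A bounded traversable 2D region.

    Attributes
    ----------
    outer : (V, 2) array
        Outer boundary polygon, positively (counter-clockwise) oriented,
        not closed (first vertex not repeated).
    barriers : list of (K, 2) arrays
        Open polyline obstacles of zero width inside the arena.
    voids : list of (V, 2) arrays
        Closed holes excluded from the traversable space.
    name : str
        Human-readable label.
    """

    outer: np.ndarray
    barriers: list = field(default_factory=list)
    voids: list = field(default_factory=list)
    name: str = "custom"
    units: str = "cm"

    def __post_init__(self):
        self.outer = np.asarray(self.outer, dtype=float)
        if self.outer.ndim != 2 or self.outer.shape[1] != 2 or len(self.outer) < 3:
            raise ValueError("outer boundary must be an (V>=3, 2) vertex array")
        ring = Polygon(self.outer)
        if not ring.is_valid:
            raise ValueError("outer boundary must be simple (non-self-intersecting)")
        if not ring.exterior.is_ccw:
            self.outer = self.outer[::-1].copy()
            ring = Polygon(self.outer)
        self.barriers = [np.asarray(b, dtype=float) for b in self.barriers]
        self.voids = [np.asarray(v, dtype=float) for v in self.voids]
        for v in self.voids:
            hole = Polygon(v)
            if not hole.is_valid or not ring.contains(hole):
                raise ValueError("voids must be simple and lie strictly inside the outer boundary")
        self._region = Polygon(self.outer, holes=[v for v in self.voids])
        if self._region.area <= 0:
            raise ValueError("traversable area must be positive")
        self._geometry: Optional[FastGeometry] = None

    # -- cached derived geometry ------------------------------------------
    @property
    def region(self) -> Polygon:
        """Traversable space as a shapely polygon (voids as holes)."""
        return self._region

    @property
    def area(self) -> float:
        return self._region.area

    @property
    def centroid(self) -> np.ndarray:
        c = self._region.centroid
        return np.array([c.x, c.y])

    @property
    def geometry(self) -> FastGeometry:
        if self._geometry is None:
            self._geometry = FastGeometry(self.outer, self.voids, self.barriers)
        return self._geometry

    def bounds(self) -> tuple[float, float, float, float]:
        return self._region.bounds

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points uniformly over the traversable space (rejection)."""
        x0, y0, x1, y1 = self.bounds()
        out = np.empty((n, 2))
        got = 0
        frac = max(self.area / ((x1 - x0) * (y1 - y0)), 1e-3)
        while got < n:
            m = int((n - got) / frac * 1.3) + 16
            pts = rng.uniform([x0, y0], [x1, y1], size=(m, 2))
            pts = pts[self.geometry.contains_points(pts)]
            take = min(len(pts), n - got)
            out[got:got + take] = pts[:take]
            got += take
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "units": self.units,
            "outer": self.outer.tolist(),
            "barriers": [b.tolist() for b in self.barriers],
            "voids": [v.tolist() for v in self.voids],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Arena":
        outer = d["outer"]
        if isinstance(outer, dict) and "circle" in outer:
            spec = outer["circle"]
            cx, cy = spec.get("center", (0.0, 0.0))
            r = spec["diameter"] / 2.0
            t = np.linspace(0.0, 2.0 * np.pi, _CURVE_N, endpoint=False)
            outer = np.stack([cx + r * np.cos(t), cy + r * np.sin(t)], axis=1)
        return cls(
            outer=np.asarray(outer, dtype=float),
            barriers=[np.asarray(b, dtype=float) for b in d.get("barriers", [])],
            voids=[np.asarray(v, dtype=float) for v in d.get("voids", [])],
            name=d.get("name", "custom"),
            units=d.get("units", "cm"),
        )


def save_arena(arena: Arena, path) -> None:
    """Write an arena config as JSON or YAML (by file extension)."""
    path = FilePath(path)
    d = arena.to_dict()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d))


def load_arena(path) -> Arena:
    path = FilePath(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return Arena.from_dict(d)


# ---------------------------------------------------------------------------
# Standard arenas
# ---------------------------------------------------------------------------

STANDARD_ARENA_NAMES = (
    "kite", "egg", "tmaze", "circle", "circle_barrier", "void_landmark",
    "square", "regular_polygon",
)


def _circle_vertices(radius: float, center=(0.0, 0.0), n: int = _CURVE_N) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.stack([center[0] + radius * np.cos(t),
                     center[1] + radius * np.sin(t)], axis=1)


def _kite_vertices() -> np.ndarray:
    # Kite with interior angles 60 (acute), 90, 120 (obtuse), 90 degrees and
    # area equal to the 76 cm circle.  Long diagonal d along x; the two
    # right-angle corners sit at (3d/4, +-sqrt(3)d/4); area = sqrt(3) d^2 / 4.
    d = math.sqrt(4.0 * _CANONICAL_AREA / math.sqrt(3.0))
    a = np.array([0.0, 0.0])                       # 60 deg corner
    b = np.array([0.75 * d, math.sqrt(3.0) / 4.0 * d])   # 90 deg
    c = np.array([d, 0.0])                         # 120 deg corner
    e = np.array([0.75 * d, -math.sqrt(3.0) / 4.0 * d])  # 90 deg
    v = np.stack([a, e, c, b])  # counter-clockwise
    cen = np.array(Polygon(v).centroid.coords[0])
    return v - cen


def _egg_vertices() -> np.ndarray:
    # Smooth 1-RS oval with a single reflective axis and no straight edges:
    # limacon r(t) = R (1 + e cos t), e = 0.3, area matched to the kite.
    e = 0.3
    R = math.sqrt(_CANONICAL_AREA / (math.pi * (1.0 + e * e / 2.0)))
    t = np.linspace(0.0, 2.0 * np.pi, _CURVE_N, endpoint=False)
    r = R * (1.0 + e * np.cos(t))
    v = np.stack([r * np.cos(t), r * np.sin(t)], axis=1)
    cen = np.array(Polygon(v).centroid.coords[0])
    return v - cen


def _tmaze_vertices() -> np.ndarray:
    # Two 20 cm wide corridors forming a T, area matched to the kite:
    # 20 (L + M) = canonical area.
    w = 20.0
    L = 140.0                       # cross-bar length
    M = _CANONICAL_AREA / w - L     # stem length
    v = np.array([
        [-L / 2.0, 0.0], [-w / 2.0, 0.0], [-w / 2.0, -M], [w / 2.0, -M],
        [w / 2.0, 0.0], [L / 2.0, 0.0], [L / 2.0, w], [-L / 2.0, w],
    ])
    cen = np.array(Polygon(v).centroid.coords[0])
    return v - cen


def _teardrop_vertices(size: float, center, angle: float, n: int = 90) -> np.ndarray:
    # Teardrop curve x = cos t, y = sin t sin^2(t/2): a smooth 1-RS void.
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = np.cos(t)
    y = np.sin(t) * np.sin(t / 2.0) ** 2
    pts = size * np.stack([x, y], axis=1)
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    pts = pts @ rot.T + np.asarray(center)
    if not Polygon(pts).exterior.is_ccw:
        pts = pts[::-1]
    return pts


def _regular_polygon_vertices(k: int) -> np.ndarray:
    # Area-matched regular k-gon: area = k R^2 sin(2 pi / k) / 2.
    R = math.sqrt(2.0 * _CANONICAL_AREA / (k * math.sin(2.0 * math.pi / k)))
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False) + math.pi / k
    return np.stack([R * np.cos(t), R * np.sin(t)], axis=1)


def make_standard_arena(name: str, scale: float = 1.0, k: Optional[int] = None) -> Arena:
    """Build a canonical arena, uniformly scaled by ``scale``.

    Recognized names: ``kite``, ``egg``, ``tmaze``, ``circle``,
    ``circle_barrier``, ``void_landmark``, ``square``, ``regular_polygon``
    (with vertex count ``k``, also accepted inline as ``regular_polygon(k)``).
    The circle has a 76 cm default diameter; the other canonical shapes are
    matched to its area.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    name = name.strip().lower()
    if name.startswith("regular_polygon(") and name.endswith(")"):
        k = int(name[len("regular_polygon("):-1])
        name = "regular_polygon"
    barriers: list = []
    voids: list = []
    if name == "circle":
        outer = _circle_vertices(CIRCLE_DIAMETER / 2.0)
    elif name == "kite":
        outer = _kite_vertices()
    elif name == "egg":
        outer = _egg_vertices()
    elif name == "tmaze":
        outer = _tmaze_vertices()
    elif name == "circle_barrier":
        outer = _circle_vertices(CIRCLE_DIAMETER / 2.0)
        # Bent ~25 cm polyline, off-centre and rotationally asymmetric.
        barriers = [np.array([[6.0, -10.5], [14.5, -1.0], [9.5, 10.5]])]
    elif name == "void_landmark":
        outer = _circle_vertices(CIRCLE_DIAMETER / 2.0)
        voids = [_teardrop_vertices(9.0, center=(14.0, 6.0), angle=math.radians(30.0))]
    elif name == "square":
        side = math.sqrt(_CANONICAL_AREA)
        h = side / 2.0
        outer = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
    elif name == "regular_polygon":
        if k is None or k < 3:
            raise ValueError("regular_polygon requires vertex count k >= 3")
        outer = _regular_polygon_vertices(k)
    else:
        raise ValueError(f"unknown standard arena {name!r}")
    arena = Arena(
        outer=outer * scale,
        barriers=[b * scale for b in barriers],
        voids=[v * scale for v in voids],
        name=name if name != "regular_polygon" else f"regular_polygon({k})",
    )
    return arena


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def contains(arena: Arena, p, body: BodyShape = POINT_BODY, theta: float = 0.0,
             n_perimeter: int = 72) -> bool:
    """True iff the body placed at (p, theta) lies wholly in traversable space.

    A point body is a point-in-region test (voids excluded).  An elliptic
    body is accepted when its centre and ``n_perimeter`` sampled perimeter
    points all lie inside and no perimeter chord crosses a boundary edge
    (which rejects bodies straddling a zero-width barrier).
    """
    p = np.asarray(p, dtype=float)
    geom = arena.geometry
    if body.is_point:
        return bool(geom.contains_points(p[None, :])[0])
    if not geom.contains_points(p[None, :])[0]:
        return False
    pts = body.perimeter_points(p, theta, n=n_perimeter)
    if not geom.contains_points(pts).all():
        return False
    nxt = np.roll(pts, -1, axis=0)
    return not geom.segments_cross(pts, nxt).any()


def segment_crosses(arena: Arena, p0, p1) -> bool:
    """True iff the segment p0->p1 crosses the outer boundary, a barrier or
    a void boundary; endpoints outside traversable space also count."""
    p0 = np.asarray(p0, dtype=float)[None, :]
    p1 = np.asarray(p1, dtype=float)[None, :]
    return bool(arena.geometry.segments_cross(p0, p1)[0])


def rotational_asymmetry(arena: Arena, phi: float) -> float:
    """A(phi): symmetric-difference area between the traversable region and
    its rotation by ``phi`` (radians) about the region centroid, divided by
    twice the region area.  0 iff the rotation maps the region onto itself."""
    region = arena.region
    rotated = shapely.affinity.rotate(region, math.degrees(phi),
                                      origin=(region.centroid.x, region.centroid.y))
    return region.symmetric_difference(rotated).area / (2.0 * region.area)


def mean_rotational_asymmetry(arena: Arena, resolution_deg: float = 1.0,
                              tol: float = 0.02) -> AsymmetryProfile:
    """Sample A(phi) over (0 deg, 360 deg) and summarize.

    Returns the profile (1-degree resolution by default, phi = 0 excluded),
    its mean, and the rotational symmetry order.
    """
    angles = np.arange(resolution_deg, 360.0, resolution_deg)
    values = np.array([rotational_asymmetry(arena, math.radians(a)) for a in angles])
    return AsymmetryProfile(
        angles_deg=angles,
        values=values,
        mean_asymmetry=float(values.mean()),
        symmetry_order=symmetry_order(arena, tol=tol),
    )


def symmetry_order(arena: Arena, tol: float = 0.02, n_max: int = 60) -> float:
    """Largest n such that A(2 pi k / n) <= tol for all k = 1..n-1.

    Rotationally invariant regions (discretized circles) are reported as the
    sentinel ``SYMMETRY_INF``.
    """
    if not (0.0 < tol <= 0.05):
        raise ValueError(f"tol must be in (0, 0.05], got {tol}")
    cache: dict[float, float] = {}

    def A(phi_deg: float) -> float:
        key = round(phi_deg, 6)
        if key not in cache:
            cache[key] = rotational_asymmetry(arena, math.radians(phi_deg))
        return cache[key]

    for n in range(n_max, 1, -1):
        if A(360.0 / n) > tol:
            continue
        if all(A(360.0 * kk / n) <= tol for kk in range(2, n)):
            # orders at the cap that are also invariant under generic small
            # rotations are rotationally invariant regions (circles)
            if n == n_max and all(A(a) <= tol for a in (2.5, 7.0, 33.0)):
                return SYMMETRY_INF
            return n
    return 1


def expand_arena(arena: Arena, sx: float, sy: float) -> Arena:
    """Scale the arena by (sx, sy) about its traversable centroid."""
    if sx <= 0 or sy <= 0:
        raise ValueError("scale factors must be positive")
    c = arena.centroid

    def sc(v: np.ndarray) -> np.ndarray:
        return (v - c) * np.array([sx, sy]) + c

    return Arena(
        outer=sc(arena.outer),
        barriers=[sc(b) for b in arena.barriers],
        voids=[sc(v) for v in arena.voids],
        name=f"{arena.name}_x{sx:g}_{sy:g}" if (sx, sy) != (1.0, 1.0) else arena.name,
    )
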