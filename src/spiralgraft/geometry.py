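"""Parametric spiral-ridged graft lumens under a constant total ridge area.

A spiral-flow graft induces swirl with one or more helical ridges protruding
from the internal wall of an otherwise straight tube (lumen diameter 6 mm).
To compare ridge designs fairly, every configuration keeps the *total* ridge
cross-sectional area fixed (3.157 mm² by default — the area of a single
circular ridge of radius 1.5 mm whose centre sits on a 3 mm-radius lumen
circle). The flow resistance, and hence the pressure drop, is then nearly the
same across designs.

A ridge cross-section is a circle or ellipse centred exactly ON the lumen
circle (centre-to-centre distance = lumen radius); its contribution to
blockage is the lens-shaped intersection with the lumen disc. This module
provides:

* closed-form circle–circle lens area and a polygon-clipped ellipse–disc area;
* root solvers for the ridge radius (multi-ridge designs) and for the
  tangential semi-axis of an elliptical ridge at fixed radial semi-axis;
* the helical ridge path (pitch H, handedness, trailing-edge orientation);
* cross-section profiles along the graft and a watertight triangulated
  surface export (STL via trimesh);
* monitoring-plane placement in the host artery (1, 5, 50 mm distal of the
  anastomosis toe).

Angular convention: 0° at the toe line, 180° at the heel line, measured
positive anticlockwise when viewed looking downstream. Lengths are in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon

__all__ = [
    "RidgeShape",
    "Handedness",
    "GraftSpec",
    "RidgeDesign",
    "CrossSectionProfile",
    "MonitoringPlane",
    "RIDGE_TOTAL_AREA",
    "circle_lens_area",
    "ellipse_lumen_intersection_area",
    "solve_circular_radius",
    "solve_ellipse_tangential_axis",
    "ridge_helix_path",
    "cross_section_at",
    "build_graft_surface",
    "place_monitoring_planes",
]

#: Total ridge cross-sectional area held constant across designs [mm^2]
#: (single circular ridge, r = 1.5 mm on a 3 mm lumen circle).
RIDGE_TOTAL_AREA = 3.157


class RidgeShape(str, Enum):
    CIRCULAR = "circular"
    ELLIPTICAL = "elliptical"


class Handedness(str, Enum):
    """Sense of the helix viewed looking downstream (along the flow)."""

    CLOCKWISE = "clockwise"
    ANTICLOCKWISE = "anticlockwise"


@dataclass(frozen=True)
class GraftSpec:
    """End-to-side graft/host-artery layout (lengths in mm, angle in degrees)."""

    lumen_diameter: float = 6.0
    anastomosis_angle: float = 60.0
    graft_length: float = 180.0
    host_artery_length: float = 120.0

    def __post_init__(self) -> None:
        if self.lumen_diameter <= 0.0:
            raise ValueError("lumen_diameter must be positive")
        if not (0.0 < self.anastomosis_angle < 90.0):
            raise ValueError("anastomosis_angle must lie in (0, 90) degrees")

    @property
    def lumen_radius(self) -> float:
        return 0.5 * self.lumen_diameter


@dataclass(frozen=True)
class RidgeDesign:
    """The four design parameters of the spiral ridge plus derived dimensions.

    ``trailing_edge_orientation`` is the circumferential angle (deg) at which
    the ridge terminates at the distal end of the graft; additional ridges of a
    multi-ridge design are equally spaced 360/count apart. ``pitch`` is the
    axial length H over which the helix completes one full turn.
    """

    shape: RidgeShape = RidgeShape.CIRCULAR
    radial_semi_axis: float = 1.5  # L1 [mm]
    tangential_semi_axis: float = 1.5  # L2 [mm]
    count: int = 1
    trailing_edge_orientation: float = 180.0  # [deg]
    pitch: float = 86.54  # H [mm]
    handedness: Handedness = Handedness.CLOCKWISE
    ridge_length: float | None = None  # default: one full pitch

    def __post_init__(self) -> None:
        if self.radial_semi_axis <= 0.0 or self.tangential_semi_axis <= 0.0:
            raise ValueError("ridge semi-axes must be positive")
        if self.pitch <= 0.0:
            raise ValueError("pitch must be positive")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.shape is RidgeShape.CIRCULAR and not math.isclose(
            self.radial_semi_axis, self.tangential_semi_axis
        ):
            raise ValueError("circular ridge requires L1 == L2")
        if self.ridge_length is not None and self.ridge_length <= 0.0:
            raise ValueError("ridge_length must be positive")

    @property
    def span(self) -> float:
        """Axial extent of the ridge [mm]; defaults to one full pitch."""
        return self.pitch if self.ridge_length is None else self.ridge_length

    def ridge_angles_at_trailing_edge(self) -> np.ndarray:
        """Circumferential centre angles (deg, mod 360) at the distal end."""
        return (
            self.trailing_edge_orientation + 360.0 * np.arange(self.count) / self.count
        ) % 360.0


@dataclass(frozen=True)
class CrossSectionProfile:
    """Lumen disc minus ridge lens(es) at one axial station (mm, mm^2)."""

    lumen_radius: float
    ridge_outlines: tuple[np.ndarray, ...]  # each (n, 2) closed polygon [mm]
    net_flow_area: float

    @property
    def lumen_area(self) -> float:
        return math.pi * self.lumen_radius**2


@dataclass(frozen=True)
class MonitoringPlane:
    """Cross-section plane in the host artery, offset distal from the toe."""

    label: str
    axial_offset_from_toe: float  # [mm]


# ---------------------------------------------------------------------------
# Intersection areas


def circle_lens_area(ridge_radius: float, lumen_radius: float) -> float:
    """Area of the circle–circle lens for a wall-centred ridge [mm^2].

    The ridge circle (radius r) is centred exactly on the lumen circle
    (radius R), i.e. the centre distance is d = R. Closed form of the standard
    two-circle intersection; 0 at r = 0, and the full lumen area once the
    ridge circle covers the lumen (r >= 2R).
    """
    r, R = float(ridge_radius), float(lumen_radius)
    if R <= 0.0:
        raise ValueError("lumen_radius must be positive")
    if r < 0.0 or r > 2.0 * R:
        raise ValueError(f"ridge_radius must lie in [0, 2*lumen_radius], got {r}")
    if r == 0.0:
        return 0.0
    if r == 2.0 * R:
        return math.pi * R * R
    d = R
    # cos of half-angles at each centre (law of cosines); clip for roundoff
    cos_a = np.clip((d * d + r * r - R * R) / (2.0 * d * r), -1.0, 1.0)
    cos_b = np.clip((d * d + R * R - r * r) / (2.0 * d * R), -1.0, 1.0)
    term = (
        r * r * math.acos(cos_a)
        + R * R * math.acos(cos_b)
        - 0.5
        * math.sqrt(
            max(0.0, (-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R))
        )
    )
    return float(term)


def _ellipse_polygon(
    center: tuple[float, float],
    semi_radial: float,
    semi_tangential: float,
    angle_deg: float,
    n_vertices: int,
) -> Polygon:
    """Shapely polygon of an ellipse whose radial axis points at ``angle_deg``."""
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    a = math.radians(angle_deg)
    e_r = np.array([math.cos(a), math.sin(a)])
    e_t = np.array([-math.sin(a), math.cos(a)])
    pts = (
        np.asarray(center)
        + np.outer(semi_radial * np.cos(t), e_r)
        + np.outer(semi_tangential * np.sin(t), e_t)
    )
    return Polygon(pts)


def ellipse_lumen_intersection_area(
    radial_semi_axis: float,
    tangential_semi_axis: float,
    lumen_radius: float,
    *,
    initial_vertices: int = 4096,
    area_tol: float = 1e-6,
) -> float:
    """Area of (wall-centred ellipse) ∩ (lumen disc) by adaptive polygon clipping.

    The ellipse is centred on the lumen circle with its semi-axis L1 aligned
    radially and L2 tangentially. Both outlines are discretized and clipped
    with shapely; the vertex count doubles until the area changes by less than
    ``area_tol`` mm². Reduces to :func:`circle_lens_area` when L1 == L2.
    """
    L1, L2, R = float(radial_semi_axis), float(tangential_semi_axis), float(lumen_radius)
    if L1 <= 0.0 or L2 <= 0.0:
        raise ValueError("ellipse semi-axes must be positive")
    if R <= 0.0:
        raise ValueError("lumen_radius must be positive")

    n = int(initial_vertices)
    prev = None
    for _ in range(8):  # 4096 -> ~1M vertices max
        disc = Point(0.0, 0.0).buffer(R, quad_segs=n // 4)
        ell = _ellipse_polygon((R, 0.0), L1, L2, 0.0, n)
        area = disc.intersection(ell).area
        if prev is not None and abs(area - prev) < area_tol:
            return float(area)
        prev = area
        n *= 2
    return float(prev)


# ---------------------------------------------------------------------------
# Constraint solvers


def solve_circular_radius(
    total_area: float,
    count: int,
    lumen_radius: float,
    *,
    area_tol: float = 1e-9,
) -> float:
    """Ridge radius r such that ``count`` wall-centred lenses sum to ``total_area``.

    Bisection on the monotone closed-form lens area, to |Δarea| < ``area_tol``
    mm². Raises if the per-ridge target exceeds the lumen area.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    target = total_area / count
    lumen_area = math.pi * lumen_radius**2
    if not (0.0 < target < lumen_area):
        raise ValueError(
            f"per-ridge area {target:.6g} mm^2 not attainable inside lumen "
            f"area {lumen_area:.6g} mm^2"
        )
    lo, hi = 0.0, 2.0 * lumen_radius
    while circle_lens_area(hi, lumen_radius) < target:  # pragma: no cover
        hi = min(hi * 1.5, 2.0 * lumen_radius)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        a = circle_lens_area(mid, lumen_radius)
        if abs(a - target) < area_tol:
            return mid
        if a < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_ellipse_tangential_axis(
    radial_semi_axis: float,
    total_area: float,
    count: int,
    lumen_radius: float,
    *,
    area_tol: float = 1e-7,
) -> float:
    """Tangential semi-axis L2 so the elliptical lens area hits the target.

    Root of ellipse_lumen_intersection_area(L1, L2, R) = total_area/count in
    L2; the area is monotone increasing in L2 so the root is bracketed in
    (0, 2R] and found by Brent's method.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    target = total_area / count
    L1, R = float(radial_semi_axis), float(lumen_radius)

    def f(L2: float) -> float:
        return ellipse_lumen_intersection_area(L1, L2, R, area_tol=area_tol) - target

    lo, hi = 1e-4, 2.0 * R
    if f(hi) < 0.0 or f(lo) > 0.0:
        raise ValueError(
            f"no tangential semi-axis in ({lo}, {hi}) mm attains per-ridge "
            f"area {target:.6g} mm^2 at L1={L1} mm"
        )
    return float(brentq(f, lo, hi, xtol=1e-7))


# ---------------------------------------------------------------------------
# Helix layout and cross-sections


def _helix_angle_deg(
    z: np.ndarray | float,
    design: RidgeDesign,
    ridge_index: int,
    z_trailing: float,
) -> np.ndarray | float:
    """Circumferential centre angle (deg) of ridge ``ridge_index`` at axial z.

    The distal (trailing-edge) end is pinned: at z = z_trailing the angle is
    trailing_edge_orientation + ridge_index*360/count. Moving upstream the
    angle advances 360°/H per pitch; clockwise handedness means the angle
    *decreases* downstream (anticlockwise-positive convention, viewed looking
    downstream).
    """
    sign = 1.0 if design.handedness is Handedness.CLOCKWISE else -1.0
    theta_te = design.trailing_edge_orientation + 360.0 * ridge_index / design.count
    return theta_te + sign * (z_trailing - np.asarray(z)) * 360.0 / design.pitch


def ridge_helix_path(
    design: RidgeDesign,
    ridge_index: int,
    axial_range: tuple[float, float],
    *,
    lumen_radius: float = 3.0,
    n_samples: int = 200,
) -> np.ndarray:
    """Sampled 3D centreline of one ridge on the lumen wall cylinder.

    Returns an (n_samples, 3) array of (x, y, z) points in mm with z the axial
    coordinate; the helix angle at the distal end of ``axial_range`` equals the
    ridge's trailing-edge angle regardless of the range length.
    """
    if not (0 <= ridge_index < design.count):
        raise ValueError(f"ridge_index must lie in [0, {design.count})")
    z0, z1 = axial_range
    if z1 <= z0:
        raise ValueError("axial_range must be increasing")
    z = np.linspace(z0, z1, n_samples)
    theta = np.radians(_helix_angle_deg(z, design, ridge_index, z1))
    return np.column_stack(
        [lumen_radius * np.cos(theta), lumen_radius * np.sin(theta), z]
    )


def cross_section_at(
    z: float,
    graft: GraftSpec,
    design: RidgeDesign,
    *,
    z_trailing: float | None = None,
    n_outline: int = 720,
) -> CrossSectionProfile:
    """Cross-section profile of the ridged lumen at axial position ``z``.

    The ridge spans ``design.span`` mm ending at ``z_trailing`` (default: the
    distal end of the graft). Outside the span the profile is the plain lumen
    disc. Ridge outlines are the lens-shaped intersections of each (rotated)
    ridge ellipse with the lumen disc, returned as closed polygons.
    """
    R = graft.lumen_radius
    if z_trailing is None:
        z_trailing = graft.graft_length
    lumen_area = math.pi * R * R
    in_span = z_trailing - design.span <= z <= z_trailing
    if not in_span:
        return CrossSectionProfile(R, (), lumen_area)

    disc = Point(0.0, 0.0).buffer(R, quad_segs=n_outline // 4)
    outlines: list[np.ndarray] = []
    total_ridge_area = 0.0
    for i in range(design.count):
        ang = float(np.asarray(_helix_angle_deg(z, design, i, z_trailing)))
        a = math.radians(ang)
        center = (R * math.cos(a), R * math.sin(a))
        ell = _ellipse_polygon(
            center, design.radial_semi_axis, design.tangential_semi_axis, ang, n_outline
        )
        lens = disc.intersection(ell)
        total_ridge_area += lens.area
        xy = np.asarray(lens.exterior.coords)
        outlines.append(xy)
    return CrossSectionProfile(R, tuple(outlines), lumen_area - total_ridge_area)


# ---------------------------------------------------------------------------
# Surface construction


def _boundary_radius(
    theta: np.ndarray,
    z: float,
    graft: GraftSpec,
    design: RidgeDesign,
    z_trailing: float,
) -> np.ndarray:
    """Radius of the flow-region boundary along each ray angle at station z.

    The ridged cross-section is star-shaped about the axis (the ridge is a
    wall-centred lens with L1 < R), so the boundary is r(theta): the lumen
    radius except where the ray first crosses a ridge ellipse. Exact
    ray–ellipse intersection, no polygon clipping.
    """
    R = graft.lumen_radius
    r = np.full_like(theta, R, dtype=float)
    if not (z_trailing - design.span <= z <= z_trailing):
        return r
    dir_x, dir_y = np.cos(theta), np.sin(theta)
    for i in range(design.count):
        ang = math.radians(float(np.asarray(_helix_angle_deg(z, design, i, z_trailing))))
        cx, cy = R * math.cos(ang), R * math.sin(ang)
        er = np.array([math.cos(ang), math.sin(ang)])
        et = np.array([-math.sin(ang), math.cos(ang)])
        L1, L2 = design.radial_semi_axis, design.tangential_semi_axis
        # ray p = t*(dx,dy); ellipse frame coords u=(p-c)·er/L1, v=(p-c)·et/L2
        du = (dir_x * er[0] + dir_y * er[1]) / L1
        dv = (dir_x * et[0] + dir_y * et[1]) / L2
        cu = (cx * er[0] + cy * er[1]) / L1
        cv = (cx * et[0] + cy * et[1]) / L2
        A = du * du + dv * dv
        B = -2.0 * (du * cu + dv * cv)
        C = cu * cu + cv * cv - 1.0
        disc = B * B - 4.0 * A * C
        hit = disc >= 0.0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t1 = (-B - sq) / (2.0 * A)
        entry = np.where(hit & (t1 > 0.0), t1, np.inf)
        r = np.minimum(r, entry)
    return r


def build_graft_surface(
    graft: GraftSpec,
    design: RidgeDesign | None,
    *,
    n_theta: int = 128,
    n_z: int = 200,
    capped: bool = True,
    z_trailing: float | None = None,
):
    """Watertight triangulated surface of the (ridged) graft lumen wall.

    Sweeps the star-shaped boundary r(theta, z) along the tube axis and
    triangulates between consecutive rings; end discs are capped with triangle
    fans so the closed surface has Euler characteristic 2. Returns a
    ``trimesh.Trimesh`` (export with ``mesh.export("graft.stl")``).

    ``design=None`` builds the plain (conventional) tube.
    """
    import trimesh

    if n_theta < 8 or n_z < 2:
        raise ValueError("resolution too coarse: need n_theta >= 8, n_z >= 2")
    if z_trailing is None:
        z_trailing = graft.graft_length
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    zs = np.linspace(0.0, graft.graft_length, n_z)

    rings = []
    for z in zs:
        if design is None:
            r = np.full_like(theta, graft.lumen_radius)
        else:
            r = _boundary_radius(theta, float(z), graft, design, z_trailing)
        rings.append(np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                      np.full_like(theta, z)]))
    verts = np.vstack(rings)

    faces = []
    for k in range(n_z - 1):
        base, nxt = k * n_theta, (k + 1) * n_theta
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            # outward-facing wall normals (viewed from outside the tube)
            faces.append([base + j, base + j2, nxt + j])
            faces.append([base + j2, nxt + j2, nxt + j])
    if capped:
        c0 = len(verts)
        verts = np.vstack([verts, [[0.0, 0.0, zs[0]], [0.0, 0.0, zs[-1]]]])
        last = (n_z - 1) * n_theta
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            faces.append([c0, j2, j])  # inlet cap
            faces.append([c0 + 1, last + j, last + j2])  # outlet cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    return mesh


def place_monitoring_planes(graft: GraftSpec | None = None) -> list[MonitoringPlane]:
    """Monitoring planes at 1, 5 and 50 mm distal of the anastomosis toe."""
    planes = [
        MonitoringPlane("plane1", 1.0),
        MonitoringPlane("plane2", 5.0),
        MonitoringPlane("plane3", 50.0),
    ]
    return planes
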