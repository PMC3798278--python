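"""Maugis-Dugdale adhesive contact between encompassing spheres.

The Dugdale cohesive-zone idealisation replaces the Lennard-Jones traction
between two elastic spheres by a constant adhesive tension sigma0 = W / h0
acting wherever the surface gap is below the effective range h0.  Inside the
intimate-contact circle of radius ``a`` the traction is Hertzian repulsion
plus the (exact) Dugdale corrective tension; on the annulus a < r <= c the
traction is exactly -sigma0; beyond the adhesive radius ``c`` it vanishes.
The transition parameter lambda interpolates continuously between the DMT
(lambda << 1, pull-off 2*pi*W*R) and JKR (lambda >> 1, pull-off 1.5*pi*W*R)
limits.

For a triangulated surface each triangle's encompassing sphere is contacted
against the other body (here a rigid plane or another sphere); ``a`` is read
directly off the sphere-sphere/sphere-plane intersection circle, ``c`` is the
root of the cohesive-zone closure equation, tractions are integrated over
the triangle with a symmetric 16-point degree-8 quadrature rule, and the
resulting force/moment pair is distributed to the triangle's nodes so both
are conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon


# ---------------------------------------------------------------------------
# material parameters
# ---------------------------------------------------------------------------

def reduced_modulus(E1: float, nu1: float, E2: float = math.inf, nu2: float = 0.0) -> float:
    """Combined (plane-strain) elastic modulus of two contacting bodies.

    1/E* = (1 - nu1^2)/E1 + (1 - nu2^2)/E2; symmetric in the two bodies, and
    E2 -> inf recovers the rigid-substrate limit E* = E1 / (1 - nu1^2).
    """
    inv = (1.0 - nu1**2) / E1
    if math.isfinite(E2):
        inv += (1.0 - nu2**2) / E2
    return 1.0 / inv


@dataclass
class MDParams:
    """Adhesive-contact material constants.

    W is the work of adhesion (J/m²), h0 the effective adhesive range (m);
    the Dugdale tension sigma0 = W / h0 follows.  E1, nu1 describe the cell
    cortex material; the default second body is rigid.
    """

    E1: float = 800e3          # Pa, cortex Young's modulus
    nu1: float = 0.4
    E2: float = math.inf       # rigid substrate by default
    nu2: float = 0.0
    W: float = 1e-3            # J/m², work of adhesion
    h0: float = 20e-9          # m, effective adhesive range

    @property
    def E_star(self) -> float:
        return reduced_modulus(self.E1, self.nu1, self.E2, self.nu2)

    @property
    def sigma0(self) -> float:
        return self.W / self.h0 if self.W > 0 else 0.0


def transition_parameter(params: MDParams, R_red: float) -> float:
    """Maugis transition parameter lambda = sigma0 (9 R / (2 pi W E*^2))^(1/3).

    lambda >> 1 is the JKR regime, lambda << 1 the DMT regime; it equals
    1.16 times the Tabor coefficient.
    """
    if params.W <= 0:
        return 0.0
    return params.sigma0 * (9.0 * R_red / (2.0 * math.pi * params.W * params.E_star**2)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# closed-form sphere results (Hertz + Maugis-Dugdale)
# ---------------------------------------------------------------------------

def hertz_pressure(r, a: float, R_red: float, params: MDParams):
    """Hertzian pressure p(r) = (2 a E* / pi R) sqrt(1 - r²/a²), 0 <= r <= a."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > a * (1 + 1e-12)):
        raise ValueError("hertz_pressure requires 0 <= r <= a")
    if a == 0.0:
        return np.zeros_like(r)
    x = np.clip(1.0 - (r / a) ** 2, 0.0, None)
    return (2.0 * a * params.E_star / (math.pi * R_red)) * np.sqrt(x)


def hertz_total_force(a: float, R_red: float, params: MDParams) -> float:
    """Total Hertz force F = 4 E* a³ / (3 R)."""
    return 4.0 * params.E_star * a**3 / (3.0 * R_red)


def _g1(m):
    """sqrt(m²-1) + (m²-2) arccos(1/m)  (cohesive-zone closure integral)."""
    s = np.sqrt(m * m - 1.0)
    return s + (m * m - 2.0) * np.arccos(1.0 / m)


def _g2(m):
    """sqrt(m²-1) arccos(1/m) - m + 1."""
    return np.sqrt(m * m - 1.0) * np.arccos(1.0 / m) - m + 1.0


def _g3(m):
    """sqrt(m²-1) + m² arccos(1/m)  (adhesive-force integral)."""
    return np.sqrt(m * m - 1.0) + m * m * np.arccos(1.0 / m)


def adhesive_radius(a: float, R_red: float, params: MDParams) -> float:
    """Adhesive radius c >= a from the cohesive-zone closure condition.

    The gap at the edge of the Dugdale zone must equal h0, which in terms of
    m = c/a reads

        (sigma0 a² / (pi W R)) g1(m) + (4 sigma0² a / (pi W E*)) g2(m) = 1.

    Solved with a bracketed scalar root finder; raises RuntimeError with the
    bracket if it cannot be enclosed.
    """
    if params.W <= 0.0:
        return a
    sigma0, W, Es = params.sigma0, params.W, params.E_star
    if a == 0.0:
        # no intimate contact: the Dugdale disc radius follows from the
        # undeformed-profile gap, c² = 2 R h0 (parabolic approximation)
        return math.sqrt(2.0 * R_red * params.h0)

    # near-static contacts re-solve the same root thousands of times; a
    # quantised memo (1e-6 relative in a and R) short-circuits that
    key = (round(math.log(a), 6), round(math.log(R_red), 6),
           sigma0, W, Es)
    cache = _c_cache
    hit = cache.get(key)
    if hit is not None:
        return hit * a

    c1 = sigma0 * a * a / (math.pi * W * R_red)
    c2 = 4.0 * sigma0 * sigma0 * a / (math.pi * W * Es)

    def f(m):
        return c1 * _g1(m) + c2 * _g2(m) - 1.0

    lo = 1.0 + 1e-14
    hi = 2.0
    it = 0
    while f(hi) < 0.0:
        hi *= 2.0
        it += 1
        if it > 60:
            raise RuntimeError(
                f"adhesive_radius: failed to bracket root, f({lo})={f(lo):.3e}, "
                f"f({hi})={f(hi):.3e}"
            )
    m = brentq(f, lo, hi, xtol=1e-300, rtol=1e-12)
    if len(cache) > 100_000:
        cache.clear()
    cache[key] = m
    return m * a


_c_cache: dict = {}


def md_net_force(a: float, R_red: float, params: MDParams, c: float | None = None) -> float:
    """Net Maugis-Dugdale force of the sphere pair at contact radius a.

    F = 4 E* a³ / (3R) - 2 sigma0 a² [sqrt(m²-1) + m² arccos(1/m)], m = c/a.
    Positive is repulsive.  For a = 0 the (attractive) Dugdale disc force
    -sigma0 pi c² is returned.
    """
    if c is None:
        c = adhesive_radius(a, R_red, params)
    if a == 0.0:
        return -params.sigma0 * math.pi * c * c
    F_h = hertz_total_force(a, R_red, params)
    if params.W <= 0.0:
        return F_h
    m = max(c / a, 1.0)
    return F_h - 2.0 * params.sigma0 * a * a * _g3(m)


def md_traction(r, a: float, c: float, R_red: float, params: MDParams):
    """Signed normal traction at in-plane radius r (tension negative).

    Hertz repulsion plus the exact Dugdale adhesive distribution
    -(2 sigma0/pi) arctan sqrt((c²-a²)/(a²-r²)) inside the contact circle,
    exactly -sigma0 on the annulus a < r <= c, zero beyond c.
    """
    r = np.asarray(r, dtype=float)
    p = np.zeros_like(r)
    sigma0 = params.sigma0

    inside = r < a
    if np.any(inside):
        ri = r[inside]
        p_h = (2.0 * a * params.E_star / (math.pi * R_red)) * np.sqrt(
            np.clip(1.0 - (ri / a) ** 2, 0.0, None)
        )
        if sigma0 > 0.0 and c > a:
            arg = (c * c - a * a) / np.maximum(a * a - ri * ri, 1e-300)
            p_adh = -(2.0 * sigma0 / math.pi) * np.arctan(np.sqrt(arg))
        else:
            p_adh = 0.0
        p[inside] = p_h + p_adh

    annulus = (~inside) & (r <= c)
    p[annulus] = -sigma0
    return p


def pull_off_force(R_red: float, params: MDParams, n_grid: int = 2000) -> float:
    """Force-control pull-off magnitude of a single MD sphere pair (N).

    Retraction under force control detaches at the first local minimum of
    the net force along the equilibrium curve F(a): the interior stationary
    minimum when one exists (JKR-like, -> 1.5 pi W R for large lambda), else
    the a -> 0 Dugdale-disc limit (DMT-like, -> 2 pi W R).
    """
    if params.W <= 0:
        return 0.0
    a_hi = (9.0 * math.pi * params.W * R_red**2 / params.E_star) ** (1.0 / 3.0)
    a = np.linspace(a_hi / n_grid, a_hi, n_grid)
    F = np.array([md_net_force(ai, R_red, params) for ai in a])
    piWR = math.pi * params.W * R_red
    interior = (F[1:-1] < F[:-2]) & (F[1:-1] < F[2:]) & (F[1:-1] < -0.5 * piWR)
    idx = np.flatnonzero(interior)
    if len(idx):
        return -float(F[idx[-1] + 1])
    # boundary: Dugdale disc at vanishing intimate contact
    c0 = math.sqrt(max(R_red**2 - (R_red - params.h0) ** 2, 0.0))
    return params.sigma0 * math.pi * c0**2


# ---------------------------------------------------------------------------
# quadrature rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratureRule:
    """Symmetric quadrature rule in barycentric coordinates.

    ``points`` is (N, 3) barycentric, ``weights`` (N,) summing to one, so
    that  ∫_T f dA ≈ area(T) Σ w_i f(q_i).
    """

    points: np.ndarray
    weights: np.ndarray
    degree: int

    @property
    def n_points(self) -> int:
        return len(self.weights)


def _sym_rule(groups) -> tuple[np.ndarray, np.ndarray]:
    pts, wts = [], []
    for w, bary in groups:
        seen = set()
        for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
            p = tuple(bary[i] for i in perm)
            if p not in seen:
                seen.add(p)
                pts.append(p)
                wts.append(w)
    return np.array(pts), np.array(wts)


def _dunavant8() -> QuadratureRule:
    # 16-point degree-8 symmetric rule (Dunavant / Zhang family)
    groups = [
        (0.144315607677787, (1 / 3, 1 / 3, 1 / 3)),
        (0.095091634413923, (0.459292588292723, 0.459292588292723, 0.081414823414554)),
        (0.103217370534718, (0.170569307751760, 0.170569307751760, 0.658861384496480)),
        (0.032458497623198, (0.050547228317031, 0.050547228317031, 0.898905543365938)),
        (0.027230314174435, (0.263112829634638, 0.728492392955404, 0.008394777409958)),
    ]
    pts, wts = _sym_rule(groups)
    wts = wts / wts.sum()     # re-normalise the tabulated digits exactly
    return QuadratureRule(points=pts, weights=wts, degree=8)


def _degree5() -> QuadratureRule:
    # classic 7-point degree-5 rule, provided for speed comparisons
    s15 = math.sqrt(15.0)
    a1 = (6.0 - s15) / 21.0
    a2 = (6.0 + s15) / 21.0
    groups = [
        (9.0 / 40.0, (1 / 3, 1 / 3, 1 / 3)),
        ((155.0 - s15) / 1200.0, (a1, a1, 1.0 - 2.0 * a1)),
        ((155.0 + s15) / 1200.0, (a2, a2, 1.0 - 2.0 * a2)),
    ]
    pts, wts = _sym_rule(groups)
    return QuadratureRule(points=pts, weights=wts, degree=5)


RULE_DEGREE8 = _dunavant8()
RULE_DEGREE5 = _degree5()

_refined_cache: dict[tuple[int, int], QuadratureRule] = {}


def refined_rule(rule: QuadratureRule, level: int) -> QuadratureRule:
    """Rule applied on a uniform 4**level split of the triangle.

    Each subdivision halves every edge, so the children have equal area and
    the composite rule keeps weights summing to one.  Used on triangles that
    straddle the contact- or adhesive-circle edge, where the traction is not
    smooth.
    """
    if level <= 0:
        return rule
    key = (id(rule), level)
    hit = _refined_cache.get(key)
    if hit is not None:
        return hit
    corners = [np.eye(3)]
    for _ in range(level):
        nxt = []
        for c in corners:
            m01, m12, m20 = (c[0] + c[1]) / 2, (c[1] + c[2]) / 2, (c[2] + c[0]) / 2
            nxt += [np.array([c[0], m01, m20]), np.array([m01, c[1], m12]),
                    np.array([m20, m12, c[2]]), np.array([m01, m12, m20])]
        corners = nxt
    pts = np.concatenate([rule.points @ c for c in corners], axis=0)
    wts = np.tile(rule.weights, len(corners)) / len(corners)
    out = QuadratureRule(points=pts, weights=wts, degree=rule.degree)
    _refined_cache[key] = out
    return out


# ---------------------------------------------------------------------------
# contact geometry
# ---------------------------------------------------------------------------

@dataclass
class Plane:
    """Rigid half-space; points with (x - point)·normal < 0 are inside it."""

    point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        self.e1, self.e2 = _plane_frame(self.normal)


@dataclass
class ContactGeometry:
    """Resolved sphere-sphere or sphere-plane contact frame."""

    delta: float          # overlap (m); negative = separation gap
    a: float              # intimate contact radius (m)
    c: float              # adhesive radius (m), c >= a
    R_red: float          # reduced radius (m)
    normal: np.ndarray    # unit, pointing from the other body into the cell
    point: np.ndarray     # contact point P, center of the intersection circle
    e1: np.ndarray        # in-plane frame vectors
    e2: np.ndarray


def _plane_frame(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(n, e1)


def sphere_plane_geometry(
    center: np.ndarray, radius: float, plane: Plane, params: MDParams
) -> ContactGeometry | None:
    """Contact frame of one encompassing sphere against a rigid plane.

    Returns None when the gap exceeds the adhesive range h0.  The reduced
    radius of a sphere-plane pair is the sphere radius itself.
    """
    n = plane.normal
    dist = float(np.dot(center - plane.point, n))     # center height above plane
    delta = radius - dist                              # >0: overlap
    if -delta > params.h0:
        return None
    if delta > 0.0:
        a = math.sqrt(max(radius * radius - dist * dist, 0.0)) if dist > 0 else radius
        c = adhesive_radius(a, radius, params)
    else:
        a = 0.0
        if params.W <= 0.0:
            return None
        # Dugdale disc from the exact spherical gap profile
        reach = radius + (-delta) - params.h0          # = dist - h0
        c = math.sqrt(max(radius * radius - reach * reach, 0.0))
        if c == 0.0:
            return None
    P = center - dist * n
    return ContactGeometry(delta=delta, a=a, c=c, R_red=radius, normal=n,
                           point=P, e1=plane.e1, e2=plane.e2)


def sphere_sphere_geometry(
    c1: np.ndarray, r1: float, c2: np.ndarray, r2: float, params: MDParams
) -> ContactGeometry | None:
    """Contact frame of two encompassing spheres (normal points from 2 to 1)."""
    d_vec = np.asarray(c1, float) - np.asarray(c2, float)
    d = float(np.linalg.norm(d_vec))
    delta = r1 + r2 - d
    if -delta > params.h0:
        return None
    n = d_vec / d
    R_red = r1 * r2 / (r1 + r2)
    if delta > 0.0:
        # radius of the sphere-sphere intersection circle
        x2 = (d * d + r2 * r2 - r1 * r1) / (2.0 * d)   # distance from c2 to plane
        a = math.sqrt(max(r2 * r2 - x2 * x2, 0.0))
        c = adhesive_radius(a, R_red, params)
        P = np.asarray(c2, float) + x2 * n
    else:
        if params.W <= 0.0:
            return None
        a = 0.0
        c = math.sqrt(max(2.0 * R_red * (params.h0 + delta), 0.0))
        if c == 0.0:
            return None
        P = np.asarray(c2, float) + (r2 - delta / 2.0 - params.h0 / 2.0) * n
    e1, e2 = _plane_frame(n)
    return ContactGeometry(delta=delta, a=a, c=c, R_red=R_red, normal=n,
                           point=P, e1=e1, e2=e2)


def detect_contact(
    tri_vertices: np.ndarray,
    sphere_center: np.ndarray,
    sphere_radius: float,
    other,
    params: MDParams,
) -> ContactGeometry | None:
    """Resolve the contact of one triangle's encompassing sphere with a body.

    ``other`` is a Plane or a (center, radius) tuple for another sphere.
    Besides the gap test against h0, the triangle itself must be close to
    the other body (within the adhesive range plus a chord-sag margin) and
    the contact disc (radius c, centered at P in the contact plane) must
    overlap the triangle's own projected footprint — sphere fragments away
    from the physical patch produce no force.
    """
    tri_vertices = np.asarray(tri_vertices, dtype=float)
    if isinstance(other, Plane):
        geom = sphere_plane_geometry(sphere_center, sphere_radius, other, params)
        gap_tri = (tri_vertices - other.point) @ other.normal
    else:
        oc, orad = other
        geom = sphere_sphere_geometry(sphere_center, sphere_radius, oc, orad, params)
        gap_tri = np.linalg.norm(tri_vertices - np.asarray(oc, float), axis=1) - orad
    if geom is None:
        return None
    area = 0.5 * np.linalg.norm(np.cross(tri_vertices[1] - tri_vertices[0],
                                         tri_vertices[2] - tri_vertices[0]))
    if gap_tri.min() > params.h0 + 0.5 * math.sqrt(2.0 * area):
        return None
    if contact_patch_area(tri_vertices, geom, geom.c) <= 0.0:
        return None
    return geom


def _project_to_plane(points: np.ndarray, geom: ContactGeometry) -> np.ndarray:
    rel = points - geom.point
    return np.stack([rel @ geom.e1, rel @ geom.e2], axis=-1)


_CIRCLE_SEGS = 64
_disc_cache: dict = {}


def _disc(radius: float):
    key = round(math.log(radius), 6)
    d = _disc_cache.get(key)
    if d is None:
        if len(_disc_cache) > 20_000:
            _disc_cache.clear()
        d = Point(0.0, 0.0).buffer(math.exp(key), quad_segs=_CIRCLE_SEGS // 4)
        _disc_cache[key] = d
    return d


def _tri_origin_distance(uv: np.ndarray) -> float:
    """2-D distance from the origin to a triangle (0 if inside)."""
    inside = True
    best = math.inf
    for k in range(3):
        p, q = uv[k], uv[(k + 1) % 3]
        e = q - p
        if p[0] * e[1] - p[1] * e[0] > 0.0:  # origin left of directed edge?
            inside = False
        t = -(p @ e) / max(e @ e, 1e-300)
        t = min(max(t, 0.0), 1.0)
        cp = p + t * e
        best = min(best, math.hypot(cp[0], cp[1]))
    # orientation of the projected triangle is arbitrary: 'inside' only if
    # the origin is on the same side of all three edges
    s = [uv[k][0] * (uv[(k + 1) % 3][1] - uv[k][1])
         - uv[k][1] * (uv[(k + 1) % 3][0] - uv[k][0]) for k in range(3)]
    if all(v >= 0 for v in s) or all(v <= 0 for v in s):
        return 0.0
    return best


def contact_patch_area(tri_vertices: np.ndarray, geom: ContactGeometry,
                       radius: float) -> float:
    """Area of the projected triangle ∩ disc of ``radius`` about P (m²)."""
    if radius <= 0.0:
        return 0.0
    uv = _project_to_plane(np.asarray(tri_vertices, float), geom)
    # cheap accept/reject before the polygon clip
    d = np.linalg.norm(uv, axis=1)
    if np.all(d <= radius):
        v0, v1, v2 = uv
        e1, e2 = v1 - v0, v2 - v0
        return abs(e1[0] * e2[1] - e1[1] * e2[0]) / 2.0
    if _tri_origin_distance(uv) >= radius:
        return 0.0
    return float(Polygon(uv).intersection(_disc(radius)).area)


def _nearest_point_in_patch(tri_uv: np.ndarray, radius: float) -> np.ndarray:
    """Point of (triangle ∩ disc) closest to the disc center, in uv coords."""
    tri = Polygon(tri_uv)
    origin = Point(0.0, 0.0)
    if tri.contains(origin):
        return np.zeros(2)
    disc = origin.buffer(radius, quad_segs=_CIRCLE_SEGS // 4)
    inter = tri.intersection(disc)
    if inter.is_empty:
        return np.zeros(2)
    from shapely.ops import nearest_points

    q = nearest_points(origin, inter)[1]
    return np.array([q.x, q.y])


# ---------------------------------------------------------------------------
# triangle force integration
# ---------------------------------------------------------------------------

@dataclass
class ContactPatch:
    """One triangle's resolved contact contribution."""

    triangle: int
    geometry: ContactGeometry
    F: np.ndarray          # (3,) force on the triangle (N), parallel to normal
    M: np.ndarray          # (3,) moment about P (N·m), in the contact plane
    A_contact: float       # projected triangle ∩ adhesive disc area (m²)
    small_contact: bool = False
    node_uv: np.ndarray | None = None   # (3, 2) node projections, frame (e1, e2)


def triangle_contact_force(
    tri_vertices: np.ndarray,
    geom: ContactGeometry,
    params: MDParams,
    rule: QuadratureRule = RULE_DEGREE8,
    triangle_index: int = -1,
    refine_level: int = 3,
    A_patch: float | None = None,
) -> ContactPatch:
    """Integrate the MD traction over one triangle.

    Resolvable contacts: quadrature of the traction over the (flat)
    triangle, evaluated at the in-plane distance of each quadrature point
    from the contact-disc center.  Triangles straddling the contact circle
    r = a or the adhesive edge r = c — where the traction is not smooth —
    are integrated with the rule refined on a uniform 4**refine_level
    split.  Contacts too small to resolve (disc area below the triangle
    area per quadrature point) fall back to the closed-form net sphere
    force scaled by the covered area fraction, applied at P or the nearest
    patch point.
    """
    tri_vertices = np.asarray(tri_vertices, dtype=float)
    n = geom.normal
    if A_patch is None:
        A_patch = contact_patch_area(tri_vertices, geom, geom.c)
    disc_area = math.pi * geom.c**2
    area = 0.5 * np.linalg.norm(
        np.cross(tri_vertices[1] - tri_vertices[0], tri_vertices[2] - tri_vertices[0])
    )

    if A_patch <= 0.0 or disc_area <= 0.0:
        return ContactPatch(triangle_index, geom, np.zeros(3), np.zeros(3), 0.0)

    uv_nodes = _project_to_plane(tri_vertices, geom)
    if disc_area < area / rule.n_points:
        # contact circle small compared to the area of one integration point
        F_tot = md_net_force(geom.a, geom.R_red, params, c=geom.c)
        frac = min(A_patch / disc_area, 1.0)
        F = F_tot * frac * n
        q_uv = _nearest_point_in_patch(uv_nodes, geom.c)
        r_vec = q_uv[0] * geom.e1 + q_uv[1] * geom.e2
        M = np.cross(r_vec, F)
        return ContactPatch(triangle_index, geom, F, M, A_patch, small_contact=True)

    r_far = float(np.linalg.norm(uv_nodes, axis=1).max())
    r_near = _tri_origin_distance(uv_nodes)
    straddles = (r_near < geom.a < r_far) or (r_near < geom.c < r_far)
    level = refine_level
    if straddles and disc_area < area:
        # small discs need leaves comparable to the disc itself
        level = max(level,
                    min(6, math.ceil(math.log(64.0 * area / disc_area, 4.0))))
    use = refined_rule(rule, level) if straddles else rule

    q = use.points @ tri_vertices                       # (Nq, 3) positions
    uv = _project_to_plane(q, geom)                     # in-plane coordinates
    r = np.linalg.norm(uv, axis=1)
    p = md_traction(r, geom.a, geom.c, geom.R_red, params)
    w = use.weights * area
    F_s = float(np.sum(w * p))
    F = F_s * n
    lever = uv[:, 0:1] * geom.e1 + uv[:, 1:2] * geom.e2  # (Nq, 3) in-plane
    M = ((w * p)[:, None] * np.cross(lever, n)).sum(axis=0)
    return ContactPatch(triangle_index, geom, F, M, A_patch)


def distribute_to_nodes(
    F: np.ndarray, M: np.ndarray, tri_vertices: np.ndarray, geom: ContactGeometry
) -> np.ndarray:
    """Split a normal force + in-plane moment over the triangle's nodes.

    Nodal forces are along the contact normal with scalar magnitudes phi_k
    solving  Σ phi_k = F·n,  Σ r_k × (phi_k n) = M  with r_k the in-plane
    node positions relative to P — a 3×3 linear system that conserves both
    total force and moment exactly.  Raises on (projected) collinear nodes.
    """
    n = geom.normal
    uv = _project_to_plane(np.asarray(tri_vertices, float), geom)
    F_s = float(F @ n)
    # moment components in the in-plane frame: M = Σ phi_k (u_k e1 + v_k e2) × n
    # with e1 × n = -e2 and e2 × n = e1:
    #   M·e1 = Σ phi_k v_k,   M·e2 = -Σ phi_k u_k
    A = np.array([
        [1.0, 1.0, 1.0],
        [uv[0, 1], uv[1, 1], uv[2, 1]],
        [-uv[0, 0], -uv[1, 0], -uv[2, 0]],
    ])
    b = np.array([F_s, float(M @ geom.e1), float(M @ geom.e2)])
    try:
        phi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "distribute_to_nodes: projected triangle nodes are collinear"
        ) from exc
    return phi[:, None] * n[None, :]


def contact_weights(tri_vertices: np.ndarray, geom: ContactGeometry,
                    floor: float = 0.0) -> np.ndarray:
    """Non-negative, normalised nodal weights of the contact point.

    The force-distribution system with unit force and zero moment yields the
    barycentric coordinates of P's projection; clamping negatives (P outside
    the triangle) and renormalising keeps the friction operator positive
    semi-definite while preserving the tie to the force distribution.  A
    positive ``floor`` is added to every weight before normalising, so that
    each node of a contacting triangle keeps a share of its drag even when
    the contact point sits at one corner.
    """
    uv = _project_to_plane(np.asarray(tri_vertices, float), geom)
    T = np.array([uv[0] - uv[2], uv[1] - uv[2]]).T
    try:
        lam = np.linalg.solve(T, -uv[2])
    except np.linalg.LinAlgError:
        return np.full(3, 1.0 / 3.0)
    w = np.array([lam[0], lam[1], 1.0 - lam[0] - lam[1]])
    w = np.clip(w, 0.0, None) + floor
    s = w.sum()
    return w / s if s > 0 else np.full(3, 1.0 / 3.0)


# ---------------------------------------------------------------------------
# whole-mesh contact resolution against a plane
# ---------------------------------------------------------------------------

def resolve_plane_contacts(
    mesh,
    spheres,
    plane: Plane,
    params: MDParams,
    rule: QuadratureRule = RULE_DEGREE8,
    refine_level: int = 3,
) -> list[ContactPatch]:
    """All per-triangle contact patches of a mesh against a rigid plane.

    Broad phase: triangles whose lowest node sits within 4*h0 + max overlap
    reach of the plane are tested; the sphere gap test and the patch clip
    do the narrow phase.
    """
    x = mesh.nodes
    n = plane.normal
    heights = (x - plane.point) @ n
    tri_min_h = heights[mesh.triangles].min(axis=1)
    # candidate triangles: physical patch close enough to the plane that a
    # point of it could lie within the adhesive range (chord-sag margin)
    areas = mesh.triangle_areas()
    margin = params.h0 + 0.5 * float(np.sqrt(areas.max()))
    cand = np.flatnonzero(tri_min_h < margin)
    patches: list[ContactPatch] = []
    if len(cand) == 0:
        return patches

    # narrow phase: per-candidate sphere-plane frames (the adhesive-radius
    # root solve is memoised, so this loop is cheap)
    idx, geoms = [], []
    for t in cand:
        geom = sphere_plane_geometry(spheres.centers[t], spheres.radii[t],
                                     plane, params)
        if geom is not None:
            idx.append(int(t))
            geoms.append(geom)
    if not idx:
        return patches
    idx = np.asarray(idx)
    verts = x[mesh.triangles[idx]]                       # (C, 3, 3)
    P = np.array([g.point for g in geoms])               # (C, 3)
    rel = verts - P[:, None, :]
    uvn = np.stack([rel @ plane.e1, rel @ plane.e2], axis=-1)   # (C, 3, 2)
    a_arr = np.array([g.a for g in geoms])
    c_arr = np.array([g.c for g in geoms])
    A_tri = areas[idx]
    d = np.linalg.norm(uvn, axis=2)                      # (C, 3) vertex radii
    r_far = d.max(axis=1)
    r_near = _tri_origin_distance_batch(uvn)
    disc_area = math.pi * c_arr**2

    outside = r_near >= c_arr
    small = (~outside) & (disc_area < A_tri / rule.n_points)
    straddle = (~outside) & (~small) & (
        ((r_near < a_arr) & (a_arr < r_far)) | (r_far > c_arr))
    smooth = (~outside) & (~small) & (~straddle)

    for name, mask, use_rule in (("smooth", smooth, rule),
                                 ("straddle", straddle,
                                  refined_rule(rule, refine_level))):
        if not mask.any():
            continue
        sel = np.flatnonzero(mask)
        uvb = uvn[sel]
        quv = np.einsum("qk,bkm->bqm", use_rule.points, uvb)   # (B, Nq, 2)
        r = np.linalg.norm(quv, axis=2)
        p = _md_traction_batch(r, a_arr[sel], c_arr[sel],
                               np.array([geoms[i].R_red for i in sel]), params)
        w = use_rule.weights[None, :] * A_tri[sel][:, None]
        Fs = np.einsum("bq,bq->b", w, p)
        wp = w * p
        Mu = np.einsum("bq,bq->b", wp, quv[:, :, 1])
        Mv = -np.einsum("bq,bq->b", wp, quv[:, :, 0])
        if name == "smooth":
            A_c = A_tri[sel]
        else:
            # covered-area estimate from the refined quadrature itself
            inside_c = r <= c_arr[sel][:, None]
            A_c = A_tri[sel] * np.einsum("q,bq->b", use_rule.weights, inside_c)
        for k, i in enumerate(sel):
            g = geoms[i]
            # lever x n = -u e2 + v e1 (right-handed in-plane frame)
            M = Mu[k] * g.e1 + Mv[k] * g.e2
            patches.append(ContactPatch(int(idx[i]), g, Fs[k] * g.normal, M,
                                        float(A_c[k]), node_uv=uvn[i]))

    for i in np.flatnonzero(small):
        t = int(idx[i])
        A_patch = contact_patch_area(x[mesh.triangles[t]], geoms[i], c_arr[i])
        if A_patch <= 0.0:
            continue
        patch = triangle_contact_force(x[mesh.triangles[t]], geoms[i], params,
                                       rule, triangle_index=t,
                                       refine_level=refine_level,
                                       A_patch=A_patch)
        patch.node_uv = uvn[i]
        patches.append(patch)
    return patches


def _tri_origin_distance_batch(uvn: np.ndarray) -> np.ndarray:
    """Vectorised 2-D distance from the origin to triangles (0 if inside)."""
    best = np.full(len(uvn), np.inf)
    signs = np.empty((len(uvn), 3))
    for k in range(3):
        p = uvn[:, k]
        q = uvn[:, (k + 1) % 3]
        e = q - p
        signs[:, k] = p[:, 0] * e[:, 1] - p[:, 1] * e[:, 0]
        t = -np.einsum("ij,ij->i", p, e) / np.maximum(
            np.einsum("ij,ij->i", e, e), 1e-300)
        cp = p + np.clip(t, 0.0, 1.0)[:, None] * e
        best = np.minimum(best, np.hypot(cp[:, 0], cp[:, 1]))
    inside = (signs >= 0).all(axis=1) | (signs <= 0).all(axis=1)
    best[inside] = 0.0
    return best


def _md_traction_batch(r, a, c, R_red, params: MDParams):
    """md_traction vectorised over rows with per-row (a, c, R)."""
    a = a[:, None]
    c = c[:, None]
    R = R_red[:, None]
    sigma0 = params.sigma0
    inside = r < a
    a_safe = np.where(a > 0.0, a, 1.0)
    p_h = (2.0 * a * params.E_star / (math.pi * R)) * np.sqrt(
        np.clip(1.0 - (r / a_safe) ** 2, 0.0, None))
    if sigma0 > 0.0:
        arg = (c * c - a * a) / np.maximum(a_safe * a_safe - r * r, 1e-300)
        p_adh = -(2.0 * sigma0 / math.pi) * np.arctan(np.sqrt(
            np.clip(arg, 0.0, None)))
    else:
        p_adh = np.zeros_like(r)
    return np.where(inside, p_h + p_adh, np.where(r <= c, -sigma0, 0.0))
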