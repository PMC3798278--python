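"""Triangulated cell surfaces: generation, curvature and bulk measures.

The cell boundary is a closed, consistently oriented triangle mesh obtained by
subdividing an icosahedron and projecting onto a sphere.  The biconcave
red-blood-cell rest shape is produced from such a sphere by quasi-static
volume deflation under linear edge springs.  Discrete mean curvature is
computed with the cotangent Laplace-Beltrami operator on mixed Voronoi areas,
and each triangle is assigned an *encompassing sphere* whose inverse radius
matches the local surface curvature; these spheres are what the adhesive
contact model acts on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh


class MeshError(ValueError):
    """Raised when a mesh violates the closed-2-manifold contract."""


# ---------------------------------------------------------------------------
# TriMesh
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Closed, outward-oriented triangulated surface.

    Attributes
    ----------
    nodes : (N, 3) float array
        Node coordinates in metres.
    triangles : (F, 3) int array
        Ordered node-index triples; counter-clockwise seen from outside.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    _edges: np.ndarray | None = field(default=None, repr=False)
    _edge_faces: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be (F, 3)")

    # -- topology -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def _build_edges(self) -> None:
        """Unique undirected edges and, per edge, its two adjacent triangles."""
        tri = self.triangles
        halfedges = np.concatenate(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]], axis=0
        )
        face_of = np.tile(np.arange(len(tri)), 3)
        key = np.sort(halfedges, axis=1)
        order = np.lexsort((key[:, 1], key[:, 0]))
        key, face_of = key[order], face_of[order]
        if len(key) % 2:
            raise MeshError("odd number of half-edges: mesh not closed")
        e0, e1 = key[0::2], key[1::2]
        if not np.array_equal(e0, e1):
            raise MeshError("an edge does not border exactly 2 triangles")
        self._edges = e0
        self._edge_faces = np.stack([face_of[0::2], face_of[1::2]], axis=1)

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) unique undirected edges (sorted node pairs)."""
        if self._edges is None:
            self._build_edges()
        return self._edges

    @property
    def edge_faces(self) -> np.ndarray:
        """(E, 2) triangle indices adjacent to each edge."""
        if self._edge_faces is None:
            self._build_edges()
        return self._edge_faces

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    def validate(self) -> None:
        """Check the closed-2-manifold invariants; raise MeshError on failure."""
        V, E, F = self.n_nodes, self.n_edges, self.n_triangles
        if V - E + F != 2:
            raise MeshError(f"Euler characteristic {V - E + F} != 2")
        # consistent orientation: every undirected edge must appear exactly
        # once in each direction among the directed half-edges
        tri = self.triangles
        he = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        directed = set(map(tuple, he))
        if len(directed) != 3 * F:
            raise MeshError("duplicate directed half-edge: inconsistent orientation")
        for a, b in self.edges:
            if (a, b) not in directed or (b, a) not in directed:
                raise MeshError("edge not traversed once in each direction")
        areas = self.triangle_areas()
        if np.any(areas <= 0):
            raise MeshError("degenerate triangle with non-positive area")
        if self.enclosed_volume() <= 0:
            raise MeshError("non-positive enclosed volume: orientation inward?")

    # -- geometry -----------------------------------------------------------

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = self.nodes
        t = self.triangles
        return x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]

    def triangle_normals(self, unit: bool = True) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        if unit:
            n = n / np.linalg.norm(n, axis=1, keepdims=True)
        return n

    def triangle_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_centroids(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return (a + b + c) / 3.0

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)

    def enclosed_volume(self) -> float:
        """Signed volume by the divergence theorem (sum of signed tetrahedra)."""
        a, b, c = self.triangle_corners()
        return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def copy(self) -> "TriMesh":
        m = TriMesh(self.nodes.copy(), self.triangles.copy())
        m._edges = self._edges
        m._edge_faces = self._edge_faces
        return m

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.nodes, self.triangles, process=False)


def enclosed_volume(mesh: TriMesh) -> float:
    """Enclosed volume (m³); raises MeshError for inward orientation."""
    v = mesh.enclosed_volume()
    if v <= 0:
        raise MeshError(f"negative enclosed volume {v}: inconsistent orientation")
    return v


def total_area(mesh: TriMesh) -> float:
    """Total surface area (m²)."""
    return mesh.total_area()


# ---------------------------------------------------------------------------
# icosphere
# ---------------------------------------------------------------------------

def icosphere(n_subdiv: int, radius: float, center=(0.0, 0.0, 0.0)) -> TriMesh:
    """Subdivided icosahedron projected on a sphere.

    Node count is 10·4**n_subdiv + 2; exactly 12 nodes keep five-fold
    connectivity, all others are six-fold.
    """
    if n_subdiv < 0:
        raise ValueError("n_subdiv must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    tm = _trimesh.creation.icosphere(subdivisions=n_subdiv, radius=radius)
    nodes = np.asarray(tm.vertices) + np.asarray(center, dtype=float)
    return TriMesh(nodes, np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# RestState
# ---------------------------------------------------------------------------

@dataclass
class RestState:
    """Stress-free reference of the cortex network."""

    L0: np.ndarray          # rest length per edge (m)
    theta0: np.ndarray      # spontaneous dihedral angle per edge (rad)
    A0_tri: np.ndarray      # rest area per triangle (m²)
    A0_total: float         # rest total area (m²)
    V0: float               # rest volume (m³)

    @classmethod
    def from_mesh(cls, mesh: TriMesh) -> "RestState":
        from .cortex import dihedral_angles  # local import avoids a cycle

        A0_tri = mesh.triangle_areas()
        return cls(
            L0=mesh.edge_lengths(),
            theta0=dihedral_angles(mesh),
            A0_tri=A0_tri,
            A0_total=float(A0_tri.sum()),
            V0=enclosed_volume(mesh),
        )


# ---------------------------------------------------------------------------
# Discrete curvature (cotangent Laplace-Beltrami, mixed Voronoi areas)
# ---------------------------------------------------------------------------

@dataclass
class CurvatureField:
    """Per-node discrete curvature data.

    K_vec is the Laplace-Beltrami vector of the coordinate functions; its
    norm is twice the mean curvature and it points outward on convex regions.
    voronoi_area holds the mixed Voronoi region of each node; corner_areas
    the per-triangle split of each triangle's area over its three corners.
    """

    K_vec: np.ndarray          # (N, 3), 1/m
    mean_curvature: np.ndarray  # (N,), 1/m, = |K_vec| / 2
    voronoi_area: np.ndarray    # (N,), m²
    corner_areas: np.ndarray    # (F, 3), m²


def curvature(mesh: TriMesh) -> CurvatureField:
    """Discrete mean-curvature normal at every node.

    Cotangent formula on the one-ring, divided by the mixed Voronoi area:
    for obtuse triangles the circumcentric region is replaced by the
    half/quarter-area rule so corner areas always partition the triangle.
    """
    x = mesh.nodes
    tri = mesh.triangles
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise MeshError(f"degenerate (zero-area) triangle {bad}")

    i0, i1, i2 = tri[:, 0], tri[:, 1], tri[:, 2]
    p0, p1, p2 = x[i0], x[i1], x[i2]

    # cotangent of the interior angle at each corner
    def _cot(a, b, c):
        """cot of angle at a, formed by rays a->b and a->c."""
        u, v = b - a, c - a
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        return np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-300)

    cot0 = _cot(p0, p1, p2)
    cot1 = _cot(p1, p2, p0)
    cot2 = _cot(p2, p0, p1)

    # mixed Voronoi corner areas
    l0sq = np.einsum("ij,ij->i", p2 - p1, p2 - p1)  # edge opposite corner 0
    l1sq = np.einsum("ij,ij->i", p0 - p2, p0 - p2)
    l2sq = np.einsum("ij,ij->i", p1 - p0, p1 - p0)
    # circumcentric Voronoi area at corner 0 uses the two edges incident to
    # it, each weighted by the cotangent of the opposite angle
    a0 = (l2sq * cot2 + l1sq * cot1) / 8.0
    a1 = (l0sq * cot0 + l2sq * cot2) / 8.0
    a2 = (l1sq * cot1 + l0sq * cot0) / 8.0
    corner = np.stack([a0, a1, a2], axis=1)

    obtuse = np.stack([cot0, cot1, cot2], axis=1) < 0.0
    any_obtuse = obtuse.any(axis=1)
    if np.any(any_obtuse):
        half = areas[any_obtuse] * 0.5
        quarter = areas[any_obtuse] * 0.25
        mixed = np.where(obtuse[any_obtuse], half[:, None], quarter[:, None])
        corner[any_obtuse] = mixed

    voronoi = np.zeros(mesh.n_nodes)
    np.add.at(voronoi, tri.ravel(), corner.ravel())

    # cotangent Laplacian: edge opposite corner k carries weight cot(k)
    K = np.zeros_like(x)
    for (ia, ib), cot in (((i1, i2), cot0), ((i2, i0), cot1), ((i0, i1), cot2)):
        w = cot[:, None] * (x[ia] - x[ib])
        np.add.at(K, ia, w)
        np.add.at(K, ib, -w)
    K /= 2.0 * voronoi[:, None]

    H = 0.5 * np.linalg.norm(K, axis=1)
    return CurvatureField(K_vec=K, mean_curvature=H, voronoi_area=voronoi,
                          corner_areas=corner)


def outward_normals(mesh: TriMesh, curv: CurvatureField | None = None) -> np.ndarray:
    """Unit outward node normals from the Laplace-Beltrami direction.

    Falls back to area-weighted face normals where |K| vanishes (flat spots).
    """
    if curv is None:
        curv = curvature(mesh)
    n = curv.K_vec.copy()
    norms = np.linalg.norm(n, axis=1)
    flat = norms < 1e-9 * max(float(np.median(norms)), 1e-300)
    if np.any(flat):
        fn = mesh.triangle_normals(unit=False)
        acc = np.zeros_like(mesh.nodes)
        np.add.at(acc, mesh.triangles.ravel(), np.repeat(fn, 3, axis=0))
        acc /= np.maximum(np.linalg.norm(acc, axis=1, keepdims=True), 1e-300)
        n[flat] = acc[flat]
        norms = np.linalg.norm(n, axis=1)
    return n / norms[:, None]


# ---------------------------------------------------------------------------
# Encompassing spheres
# ---------------------------------------------------------------------------

@dataclass
class EncompassingSpheres:
    """Per-triangle curvature-matched spheres (struct-of-arrays)."""

    centers: np.ndarray   # (F, 3)
    radii: np.ndarray     # (F,)
    curvatures: np.ndarray  # (F,) clamped triangle mean curvature (1/m)


def encompassing_spheres(
    mesh: TriMesh, curv: CurvatureField | None = None, kappa_min: float | None = None
) -> EncompassingSpheres:
    """Sphere per triangle with inverse curvature matching the surface.

    Triangle curvature is the Voronoi-area-weighted mean of the corner mean
    curvatures, clamped below by ``kappa_min`` (default 0.2 / mean mesh
    radius, i.e. radii capped at five cell radii).  The center sits on the
    inward side of the triangle plane so that all three corners lie on the
    sphere: for radii below the circumradius the radius is raised to it.
    """
    if curv is None:
        curv = curvature(mesh)
    if kappa_min is None:
        r_cell = np.linalg.norm(mesh.nodes - mesh.nodes.mean(axis=0), axis=1).mean()
        kappa_min = 0.2 / r_cell
    if kappa_min <= 0:
        raise ValueError("kappa_min must be > 0")

    tri = mesh.triangles
    H = curv.mean_curvature[tri]                     # (F, 3)
    w = curv.corner_areas                            # (F, 3)
    wsum = w.sum(axis=1)
    kappa = np.einsum("ij,ij->i", w, H) / np.maximum(wsum, 1e-300)
    kappa = np.maximum(kappa, kappa_min)

    a, b, c = mesh.triangle_corners()
    n = mesh.triangle_normals()

    # circumcenter in the triangle plane
    ab, ac = b - a, c - a
    abab = np.einsum("ij,ij->i", ab, ab)
    acac = np.einsum("ij,ij->i", ac, ac)
    abac = np.einsum("ij,ij->i", ab, ac)
    det = 2.0 * (abab * acac - abac**2)
    s = (acac * (abab - abac)) / det
    t = (abab * (acac - abac)) / det
    circum = a + s[:, None] * ab + t[:, None] * ac
    r_circ = np.linalg.norm(circum - a, axis=1)

    radius = np.maximum(1.0 / kappa, r_circ * (1.0 + 1e-12))
    h = np.sqrt(np.maximum(radius**2 - r_circ**2, 0.0))
    centers = circum - n * h[:, None]
    return EncompassingSpheres(centers=centers, radii=radius, curvatures=1.0 / radius)


# ---------------------------------------------------------------------------
# Biconcave deflation
# ---------------------------------------------------------------------------

@dataclass
class DeflationParams:
    """Relaxation schedule for sphere → biconcave deflation.

    The enclosed volume is constrained exactly (scalar projection along the
    node normals each step) to a target that is ramped down linearly, while
    linear edge springs keep the surface area near its spherical value and
    a weak flat-favouring bending term regularises the dimples into an
    axisymmetric discocyte.  The pseudo-dynamics are dimensionless (unit
    mobility); ``k_spring`` and ``k_bend`` are rates, not physical
    stiffnesses.
    """

    k_spring: float = 1.0        # linear edge-spring rate
    k_bend: float = 0.1          # zero-spontaneous-angle dihedral bending rate
    k_area: float = 2.0          # local-area restoring rate
    guide: float = 0.1           # oblate guide force rate during the ramp
    dt: float = 0.1              # pseudo-time step
    n_ramp: int = 2000           # steps over which the target volume ramps
    n_relax: int = 4000          # additional relaxation steps
    squash: float = 0.98         # initial z-scaling seeding the symmetry axis
    vol_tol: float = 1e-3        # relative volume tolerance at convergence
    residual_tol: float = 5e-3   # max node displacement per step / L0 at end


def deflate_to_biconcave(
    mesh: TriMesh,
    volume_fraction: float = 0.6,
    params: DeflationParams | None = None,
    history: list | None = None,
) -> TriMesh:
    """Deflate a spherical mesh to ``volume_fraction`` of its volume.

    The enclosed volume is ramped down (exactly constrained by a normal
    projection each step) while linear edge springs and a local-area
    restoring term conserve the surface area and a zero-spontaneous-angle
    dihedral bending term selects the smooth, axisymmetric buckling mode:
    at reduced volume ~0.6 the minimiser is the classic biconcave
    discocyte, with symmetry axis along z.  A weak oblate guide force,
    active only during the ramp, deterministically orients the buckling;
    it is released for the final relaxation.  Raises RuntimeError with a
    residual report if the relaxation does not converge.
    """
    if not (0.0 < volume_fraction <= 1.0):
        raise ValueError("volume_fraction must be in (0, 1]")
    p = params or DeflationParams()

    out = mesh.copy()
    if volume_fraction == 1.0:
        return out

    x = out.nodes
    center = x.mean(axis=0)
    x -= center
    V0 = out.enclosed_volume()
    V_target_final = volume_fraction * V0
    L0 = out.edge_lengths()
    L_char = float(L0.mean())
    r_mean = float(np.linalg.norm(x, axis=1).mean())

    x[:, 2] *= p.squash  # deterministic axisymmetric seed for the buckling

    e0, e1 = out.edges[:, 0], out.edges[:, 1]
    from .cortex import CortexParams, area_constraint_forces, bending_forces

    rest0 = RestState.from_mesh(mesh)
    rest_flat = RestState.from_mesh(mesh)
    rest_flat.theta0 = np.zeros_like(rest_flat.theta0)
    cp_bend = CortexParams(kb=p.k_bend * L_char**2)
    cp_area = CortexParams(ka_local=p.k_area / np.sqrt(rest0.A0_tri.mean()),
                           ka_global=0.0)

    def _project_volume(target: float) -> None:
        # Newton steps on x -> x + mu * n_hat (n_hat = normalised volume
        # gradient, the node's area-weighted outward normal) until V = target
        for _ in range(4):
            V = out.enclosed_volume()
            if abs(V - target) < 1e-12 * V0:
                return
            gv = np.zeros_like(x)
            a, b, c = out.triangle_corners()
            t = out.triangles
            np.add.at(gv, t[:, 0], np.cross(b, c) / 6.0)
            np.add.at(gv, t[:, 1], np.cross(c, a) / 6.0)
            np.add.at(gv, t[:, 2], np.cross(a, b) / 6.0)
            nrm = gv / np.maximum(np.linalg.norm(gv, axis=1, keepdims=True), 1e-300)
            dVdmu = float(np.einsum("ij,ij->", nrm, gv))
            x[...] += ((target - V) / dVdmu) * nrm

    n_steps = p.n_ramp + p.n_relax
    last_disp = np.inf
    for step in range(n_steps):
        frac = min(1.0, (step + 1) / p.n_ramp)
        V_target = V0 + frac * (V_target_final - V0)

        # all terms carry units of length: dx = dt * F is a displacement
        d = x[e1] - x[e0]
        L = np.linalg.norm(d, axis=1)
        u = d / L[:, None]
        f_edge = (p.k_spring * (L - L0))[:, None] * u
        F = np.zeros_like(x)
        np.add.at(F, e0, f_edge)
        np.add.at(F, e1, -f_edge)
        if p.k_bend:
            F += bending_forces(out, rest_flat, cp_bend)
        if p.k_area:
            F += area_constraint_forces(out, rest0, cp_area)
        if p.guide and step < p.n_ramp:
            F[:, 2] -= p.guide * (L_char / r_mean) * x[:, 2]
        dx = p.dt * F
        last_disp = float(np.abs(dx).max()) / L_char
        x += dx
        _project_volume(V_target)
        if history is not None:
            history.append((step, out.enclosed_volume()))

    V = out.enclosed_volume()
    vol_err = abs(V - V_target_final) / V_target_final
    if vol_err > p.vol_tol or last_disp > p.residual_tol:
        raise RuntimeError(
            "biconcave deflation did not converge: "
            f"relative volume error {vol_err:.2e} (tol {p.vol_tol:.0e}), "
            f"final step displacement {last_disp:.2e} L0 (tol {p.residual_tol:.0e})"
        )
    x += center
    return out
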