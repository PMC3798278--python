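"""Viscoelastic cortex forces on the triangulated spectrin network.

Edges are Kelvin-Voigt elements: a finitely extensible nonlinear elastic
(FENE) spring in parallel with an axial dashpot, plus a power-law repulsion
that balances the FENE attraction at the rest length.  Adjacent-triangle
pairs carry a dihedral bending moment; local and global area penalties keep
triangle and total membrane area near their rest values, and a volume
penalty keeps the enclosed cytosol volume constant on short time scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import CurvatureField, RestState, TriMesh, curvature, outward_normals


class OverstretchError(RuntimeError):
    """An edge reached its maximal FENE extension (time step too large)."""


def _scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """out[idx] += vals for (M, 3) vals — bincount beats np.add.at here."""
    n = len(out)
    for k in range(3):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


@dataclass
class CortexParams:
    """Cortex material constants (SI).

    ks : FENE stretching constant (N/m); the spectrin network is of order
         1 µN/m.
    x0 : maximal stretch ratio L_max / L0 at which the FENE force diverges.
    m_pow : exponent of the power-law repulsion that models the limited
         compressibility of spectrin.
    kb : bending constant (N·m) of the dihedral moment kb (theta - theta0).
    c_damp : Kelvin-Voigt dashpot constant (N·s/m) on each edge.
    ka_local / ka_global : area penalty constants (N/m²).
    kv : volume penalty constant (Pa): the restoring pressure per unit
         relative volume deficit.  The default conserves the cytosol volume
         to well under a percent in the spreading runs.
    """

    ks: float = 3.2e-6
    x0: float = 2.05
    m_pow: int = 2
    kb: float = 240e-21
    c_damp: float = 1.5e-6
    ka_local: float = 6e3
    ka_global: float = 6e3
    kv: float = 5e3
    gravity: np.ndarray | None = None   # optional per-unit-node force hook (N)


# ---------------------------------------------------------------------------
# FENE + power-law edge elasticity
# ---------------------------------------------------------------------------

def _kc(L0, p: CortexParams):
    """Repulsion coefficient making the net edge force vanish at L = L0."""
    return p.ks * L0 ** (p.m_pow + 1) / (1.0 - p.x0 ** -2)


def fene_potential(L, L0, p: CortexParams):
    """Elastic edge energy: FENE attraction + power-law repulsion (J)."""
    L = np.asarray(L, dtype=float)
    Lmax = p.x0 * np.asarray(L0, dtype=float)
    u_fene = -0.5 * p.ks * Lmax**2 * np.log(1.0 - (L / Lmax) ** 2)
    kc = _kc(np.asarray(L0, dtype=float), p)
    if p.m_pow == 1:
        u_rep = -kc * np.log(L)
    else:
        u_rep = kc / ((p.m_pow - 1) * L ** (p.m_pow - 1))
    return u_fene + u_rep


def edge_elastic_force(L, L0, p: CortexParams):
    """Signed scalar edge force (N); positive pushes the nodes apart.

    kc / L^m  -  ks L / (1 - (L/Lmax)²), zero at L = L0 by construction of
    kc.  Raises OverstretchError at L >= x0 L0.
    """
    L = np.asarray(L, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    if np.any(L >= p.x0 * L0):
        worst = float((L / L0).max())
        raise OverstretchError(
            f"edge stretch {worst:.3f} reached the FENE limit x0 = {p.x0}"
        )
    if np.any(L <= 0):
        raise ValueError("edge length must be positive")
    attract = p.ks * L / (1.0 - (L / (p.x0 * L0)) ** 2)
    repel = _kc(L0, p) / L**p.m_pow
    return repel - attract


def edge_tension(L, L0, p: CortexParams):
    """Tensile-positive edge force (N): the negative of edge_elastic_force."""
    return -edge_elastic_force(L, L0, p)


def edge_dashpot_force(v_rel_axial, p: CortexParams):
    """Axial dashpot force magnitude c_damp · v_rel (N), opposing relative
    motion along the connection; equal and opposite on the two nodes."""
    return p.c_damp * np.asarray(v_rel_axial, dtype=float)


# ---------------------------------------------------------------------------
# dihedral bending
# ---------------------------------------------------------------------------

@dataclass
class BendingTopology:
    """Per-interior-edge stencil: shared nodes (a, b) as traversed by the
    first adjacent face, and the opposite nodes p (face 1) / q (face 2)."""

    a: np.ndarray
    b: np.ndarray
    p: np.ndarray
    q: np.ndarray

    @classmethod
    def from_mesh(cls, mesh: TriMesh) -> "BendingTopology":
        tri = mesh.triangles
        edges = mesh.edges
        faces = mesh.edge_faces
        f1, f2 = faces[:, 0], faces[:, 1]
        t1, t2 = tri[f1], tri[f2]
        u, v = edges[:, 0], edges[:, 1]

        # orientation of (u, v) as traversed by face 1
        a = np.empty_like(u)
        b = np.empty_like(u)
        for k in range(3):
            nxt = (k + 1) % 3
            m = (t1[:, k] == u) & (t1[:, nxt] == v)
            a[m], b[m] = u[m], v[m]
            m = (t1[:, k] == v) & (t1[:, nxt] == u)
            a[m], b[m] = v[m], u[m]

        def _opposite(t, na, nb):
            opp = t.sum(axis=1) - na - nb
            return opp

        return cls(a=a, b=b, p=_opposite(t1, a, b), q=_opposite(t2, a, b))


_topo_cache: dict[int, tuple[tuple[int, int], BendingTopology]] = {}


def _topology(mesh: TriMesh) -> BendingTopology:
    key = id(mesh.triangles)
    shape = (mesh.n_nodes, mesh.n_triangles)
    hit = _topo_cache.get(key)
    if hit is not None and hit[0] == shape:
        return hit[1]
    topo = BendingTopology.from_mesh(mesh)
    _topo_cache[key] = (shape, topo)
    return topo


def _dihedral_geometry(mesh: TriMesh, topo: BendingTopology):
    x = mesh.nodes
    xa, xb, xp, xq = x[topo.a], x[topo.b], x[topo.p], x[topo.q]
    e = xb - xa
    elen = np.linalg.norm(e, axis=1)
    n1 = np.cross(e, xp - xa)            # face-1 normal (points outward for
    n2 = np.cross(xq - xa, e)            # CCW faces), face-2 likewise
    n1n = np.linalg.norm(n1, axis=1)
    n2n = np.linalg.norm(n2, axis=1)
    if np.any(n1n <= 0) or np.any(n2n <= 0):
        raise ValueError("degenerate dihedral: collapsed triangle")
    n1u = n1 / n1n[:, None]
    n2u = n2 / n2n[:, None]
    ehat = e / elen[:, None]
    sin_t = np.einsum("ij,ij->i", np.cross(n1u, n2u), ehat)
    cos_t = np.einsum("ij,ij->i", n1u, n2u)
    theta = np.arctan2(sin_t, cos_t)
    return xa, xb, xp, xq, e, elen, ehat, n1u, n2u, n1n, n2n, theta


def dihedral_angles(mesh: TriMesh) -> np.ndarray:
    """Signed dihedral angle per edge (rad); 0 for coplanar faces, positive
    for a convex fold (outward normals splaying apart)."""
    topo = _topology(mesh)
    return _dihedral_geometry(mesh, topo)[-1]


def bending_forces(
    mesh: TriMesh, rest: RestState, p: CortexParams, return_energy: bool = False
):
    """Nodal forces of the dihedral bending moments kb (theta - theta0).

    The force on each opposite node is normal to its triangle with magnitude
    moment / (distance to the shared edge); the edge nodes carry the exact
    compensating forces, so each 4-node stencil has zero net force and zero
    net torque (the forces are minus the gradient of
    (kb/2)(theta-theta0)²).
    """
    topo = _topology(mesh)
    (xa, xb, xp, xq, e, elen, ehat, n1u, n2u, n1n, n2n, theta) = _dihedral_geometry(
        mesh, topo
    )
    moment = p.kb * (theta - rest.theta0)

    # gradients of the dihedral angle (sign: moving xp along +n1 opens the
    # convex fold, decreasing theta under this orientation convention)
    inv_e2 = 1.0 / (elen**2)
    gp = -(elen / n1n)[:, None] * n1u                # d(theta)/d(xp)
    gq = -(elen / n2n)[:, None] * n2u
    wpa = np.einsum("ij,ij->i", xb - xp, e) * inv_e2
    wqa = np.einsum("ij,ij->i", xb - xq, e) * inv_e2
    wpb = np.einsum("ij,ij->i", xp - xa, e) * inv_e2
    wqb = np.einsum("ij,ij->i", xq - xa, e) * inv_e2
    ga = -(wpa[:, None] * gp + wqa[:, None] * gq)
    gb = -(wpb[:, None] * gp + wqb[:, None] * gq)

    F = np.zeros_like(mesh.nodes)
    mcol = -moment[:, None]
    _scatter_add(F, topo.p, mcol * gp)
    _scatter_add(F, topo.q, mcol * gq)
    _scatter_add(F, topo.a, mcol * ga)
    _scatter_add(F, topo.b, mcol * gb)
    if return_energy:
        return F, float(0.5 * p.kb * np.sum((theta - rest.theta0) ** 2))
    return F


def bending_energy(mesh: TriMesh, rest: RestState, p: CortexParams) -> float:
    theta = dihedral_angles(mesh)
    return float(0.5 * p.kb * np.sum((theta - rest.theta0) ** 2))


def bending_forces_linearized(mesh: TriMesh) -> np.ndarray:
    """Flat-favouring regulariser (units of length): umbrella Laplacian of
    the node positions projected on the node normal.  Used only by the
    sphere → biconcave deflation to smooth the dimples."""
    x = mesh.nodes
    edges = mesh.edges
    acc = np.zeros_like(x)
    cnt = np.zeros(len(x))
    np.add.at(acc, edges[:, 0], x[edges[:, 1]])
    np.add.at(acc, edges[:, 1], x[edges[:, 0]])
    np.add.at(cnt, edges.ravel(), 1.0)
    umb = acc / cnt[:, None] - x
    nrm = outward_normals(mesh)
    return np.einsum("ij,ij->i", umb, nrm)[:, None] * nrm


# ---------------------------------------------------------------------------
# area and volume penalties
# ---------------------------------------------------------------------------

def _area_gradients(mesh: TriMesh):
    """d(area)/d(node) for each triangle corner: in-plane, sums to zero."""
    a, b, c = mesh.triangle_corners()
    n = mesh.triangle_normals()
    ga = 0.5 * np.cross(n, c - b)
    gb = 0.5 * np.cross(n, a - c)
    gc = 0.5 * np.cross(n, b - a)
    return ga, gb, gc


def area_constraint_forces(
    mesh: TriMesh, rest: RestState, p: CortexParams, return_energy: bool = False
):
    """Local + global area penalty forces.

    Gradients of E_loc = Σ_T ka_local (A_T - A0_T)² / (2 sqrt(A0_T)) and
    E_glob = ka_global (A - A0)² / (2 sqrt(A0)); the normalisation by a rest
    length scale makes the N/m² constants dimensionally consistent.  The
    per-triangle force sum vanishes and every nodal force lies in its
    triangle's plane (the area gradient is in-plane, from the barycenter
    outward for near-equilateral triangles).
    """
    A = mesh.triangle_areas()
    ga, gb, gc = _area_gradients(mesh)
    coef_loc = p.ka_local * (A - rest.A0_tri) / np.sqrt(rest.A0_tri)
    A_tot = float(A.sum())
    coef_glob = p.ka_global * (A_tot - rest.A0_total) / np.sqrt(rest.A0_total)
    coef = coef_loc + coef_glob

    F = np.zeros_like(mesh.nodes)
    t = mesh.triangles
    _scatter_add(F, t[:, 0], -coef[:, None] * ga)
    _scatter_add(F, t[:, 1], -coef[:, None] * gb)
    _scatter_add(F, t[:, 2], -coef[:, None] * gc)
    if return_energy:
        e_loc = float(np.sum(p.ka_local * (A - rest.A0_tri) ** 2
                             / (2.0 * np.sqrt(rest.A0_tri))))
        e_glob = float(p.ka_global * (A_tot - rest.A0_total) ** 2
                       / (2.0 * np.sqrt(rest.A0_total)))
        return F, e_loc + e_glob
    return F


def area_energy(mesh: TriMesh, rest: RestState, p: CortexParams) -> float:
    return area_constraint_forces(mesh, rest, p, return_energy=True)[1]


def volume_gradient(mesh: TriMesh) -> np.ndarray:
    """d(enclosed volume)/d(node): one third of the node's area-weighted
    outward normal — the discrete outward direction of each node."""
    gv = np.zeros_like(mesh.nodes)
    a, b, c = mesh.triangle_corners()
    t = mesh.triangles
    _scatter_add(gv, t[:, 0], np.cross(b, c) / 6.0)
    _scatter_add(gv, t[:, 1], np.cross(c, a) / 6.0)
    _scatter_add(gv, t[:, 2], np.cross(a, b) / 6.0)
    return gv


def volume_constraint_force(
    mesh: TriMesh,
    rest: RestState,
    p: CortexParams,
    curv: CurvatureField | None = None,
) -> np.ndarray:
    """Pressure-like volume restoring force on every node.

    f_i = kv ((V0 - V)/V0) dV/dx_i: the gradient of the penalty
    E = kv V0 ((V - V0)/V0)² / 2, i.e. an internal pressure kv (Pa) per unit
    relative volume deficit, applied along each node's outward direction.
    """
    V = mesh.enclosed_volume()
    return (p.kv * (rest.V0 - V) / rest.V0) * volume_gradient(mesh)


def volume_energy(mesh: TriMesh, rest: RestState, p: CortexParams) -> float:
    V = mesh.enclosed_volume()
    return float(0.5 * p.kv * (V - rest.V0) ** 2 / rest.V0)


# ---------------------------------------------------------------------------
# aggregate
# ---------------------------------------------------------------------------

@dataclass
class CortexForces:
    """Per-contribution nodal force fields plus derived observables."""

    fene: np.ndarray
    bending: np.ndarray
    area: np.ndarray
    volume: np.ndarray
    tension: np.ndarray      # per-node cortex tension (N/m)
    stretch: np.ndarray      # per-edge L / L0

    @property
    def total(self) -> np.ndarray:
        return self.fene + self.bending + self.area + self.volume


def elastic_forces(
    mesh: TriMesh,
    rest: RestState,
    p: CortexParams,
    curv: CurvatureField | None = None,
) -> CortexForces:
    """All conservative cortex force contributions on the current shape."""
    x = mesh.nodes
    e0, e1 = mesh.edges[:, 0], mesh.edges[:, 1]
    d = x[e1] - x[e0]
    L = np.linalg.norm(d, axis=1)
    u = d / L[:, None]

    f_scalar = edge_elastic_force(L, rest.L0, p)   # positive pushes apart
    fe = f_scalar[:, None] * u
    F_fene = np.zeros_like(x)
    _scatter_add(F_fene, e0, -fe)
    _scatter_add(F_fene, e1, fe)

    F_bend = bending_forces(mesh, rest, p)
    F_area = area_constraint_forces(mesh, rest, p)
    F_vol = volume_constraint_force(mesh, rest, p, curv)

    T = cortex_tension(mesh, rest, p, L=L)
    return CortexForces(fene=F_fene, bending=F_bend, area=F_area, volume=F_vol,
                        tension=T, stretch=L / rest.L0)


def dashpot_dissipation(mesh: TriMesh, velocities: np.ndarray, p: CortexParams) -> float:
    """Instantaneous power dissipated in all edge dashpots (W, >= 0)."""
    e0, e1 = mesh.edges[:, 0], mesh.edges[:, 1]
    d = mesh.nodes[e1] - mesh.nodes[e0]
    u = d / np.linalg.norm(d, axis=1)[:, None]
    v_ax = np.einsum("ij,ij->i", velocities[e1] - velocities[e0], u)
    return float(np.sum(p.c_damp * v_ax**2))


def cortex_tension(
    mesh: TriMesh, rest: RestState, p: CortexParams, L: np.ndarray | None = None
) -> np.ndarray:
    """Node-averaged in-plane cortex tension (N/m), tensile positive.

    The tensile edge force divided by the inter-nodal distance, averaged
    over the FENE connections of each node."""
    e0, e1 = mesh.edges[:, 0], mesh.edges[:, 1]
    if L is None:
        L = mesh.edge_lengths()
    t_edge = edge_tension(L, rest.L0, p) / L
    T = np.zeros(mesh.n_nodes)
    cnt = np.zeros(mesh.n_nodes)
    np.add.at(T, e0, t_edge)
    np.add.at(T, e1, t_edge)
    np.add.at(cnt, np.concatenate([e0, e1]), 1.0)
    return T / np.maximum(cnt, 1.0)


def elastic_energy(mesh: TriMesh, rest: RestState, p: CortexParams) -> float:
    """Total conservative cortex energy (FENE + repulsion + bending + area)."""
    L = mesh.edge_lengths()
    e_edge = float(np.sum(fene_potential(L, rest.L0, p)
                          - fene_potential(rest.L0, rest.L0, p)))
    return (e_edge + bending_energy(mesh, rest, p) + area_energy(mesh, rest, p)
            + volume_energy(mesh, rest, p))
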