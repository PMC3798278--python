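"""Maugis-Dugdale theory, quadrature and force distribution."""

import math

import numpy as np
import pytest

from mdcell.contact import (MDParams, Plane, QuadratureRule, RULE_DEGREE5,
                            RULE_DEGREE8, adhesive_radius, contact_weights,
                            detect_contact, distribute_to_nodes,
                            hertz_pressure, hertz_total_force, md_net_force,
                            md_traction, pull_off_force, reduced_modulus,
                            sphere_plane_geometry, sphere_sphere_geometry,
                            transition_parameter, triangle_contact_force)

R = 3.25e-6
TABLE = MDParams()          # W = 1e-3 J/m², h0 = 20 nm, E = 800 kPa, nu = 0.4


class TestReducedModulus:
    def test_identical_bodies_zero_poisson(self):
        assert reduced_modulus(1e5, 0.0, 1e5, 0.0) == pytest.approx(5e4)

    def test_rigid_limit(self):
        assert reduced_modulus(8e5, 0.4) == pytest.approx(8e5 / (1 - 0.4**2))

    def test_symmetry(self):
        assert reduced_modulus(1e5, 0.3, 4e5, 0.45) == pytest.approx(
            reduced_modulus(4e5, 0.45, 1e5, 0.3))

    def test_rbc_default_modulus(self):
        assert TABLE.E_star == pytest.approx(800e3 / 0.84)


class TestTransitionParameter:
    def test_homogeneity_in_sigma0(self):
        # at fixed W, R, E*, lambda is linear in sigma0 (halving h0 doubles it)
        lam1 = transition_parameter(TABLE, R)
        half = MDParams(W=TABLE.W, h0=TABLE.h0 / 2)
        assert transition_parameter(half, R) == pytest.approx(2 * lam1, rel=1e-12)

    def test_dimensionless_under_unit_rescaling(self):
        s, f = 1e6, 1e12             # length and force rescaling
        lam = transition_parameter(TABLE, R)
        scaled = MDParams(E1=TABLE.E1 * f / s**2, nu1=TABLE.nu1,
                          W=TABLE.W * f / s, h0=TABLE.h0 * s)
        assert transition_parameter(scaled, R * s) == pytest.approx(lam, rel=1e-12)

    def test_cell_scale_regime_is_transitional(self):
        # Table parameters with the curvature-matched sphere radius: the
        # contact sits between the DMT and JKR limits
        lam = transition_parameter(TABLE, R)
        assert 0.3 < lam < 3.0


class TestHertz:
    def test_pressure_edge_and_peak(self):
        a = 0.3e-6
        assert hertz_pressure(a, a, R, TABLE) == pytest.approx(0.0, abs=1e-12)
        p = hertz_pressure(np.array([0.0, a / 2]), a, R, TABLE)
        assert p[0] > p[1] > 0

    def test_no_contact_no_force(self):
        assert hertz_total_force(0.0, R, TABLE) == 0.0

    def test_outside_contact_raises(self):
        with pytest.raises(ValueError):
            hertz_pressure(1.1e-6, 1e-6, R, TABLE)

    def test_pressure_integrates_to_total_force(self, rng):
        for _ in range(5):
            a = rng.uniform(0.05e-6, 0.8e-6)
            Rr = rng.uniform(1e-6, 10e-6)
            r = np.linspace(0, a, 40001)
            F = np.trapezoid(hertz_pressure(r, a, Rr, TABLE) * 2 * np.pi * r, r)
            assert F == pytest.approx(hertz_total_force(a, Rr, TABLE), rel=1e-6)


class TestAdhesiveRadius:
    def test_no_adhesion_gives_c_equal_a(self):
        assert adhesive_radius(1e-7, R, MDParams(W=0.0)) == 1e-7

    def test_adhesive_annulus_trends(self):
        """Stronger adhesion at fixed Dugdale tension widens the annulus;
        raising the tension at fixed W contracts it toward the JKR limit."""
        a = 2e-7
        sigma0 = 5e4
        cs = [adhesive_radius(a, R, MDParams(W=w, h0=w / sigma0))
              for w in np.linspace(2e-4, 3e-3, 8)]
        assert all(c2 > c1 for c1, c2 in zip(cs, cs[1:]))
        cs_fixed_h0 = [adhesive_radius(a, R, MDParams(W=w, h0=20e-9))
                       for w in np.linspace(2e-4, 3e-3, 8)]
        assert all(c2 < c1 for c1, c2 in zip(cs_fixed_h0, cs_fixed_h0[1:]))
        assert all(c > a for c in cs + cs_fixed_h0)

    def test_consistent_with_net_force(self):
        # W -> 0 limit: net force approaches pure Hertz
        a = 3e-7
        weak = MDParams(W=1e-8)
        assert md_net_force(a, R, weak) == pytest.approx(
            hertz_total_force(a, R, weak), rel=1e-3)

    def test_pull_off_limits_bracket_jkr_dmt(self):
        piWR = math.pi * 1e-3 * R
        jkr = pull_off_force(R, MDParams(W=1e-3, h0=0.2e-9))    # lambda ~ 86
        dmt = pull_off_force(R, MDParams(W=1e-3, h0=2000e-9))   # lambda ~ 0.009
        assert jkr == pytest.approx(1.5 * piWR, rel=0.05)
        assert dmt == pytest.approx(2.0 * piWR, rel=0.05)
        table = pull_off_force(R, TABLE)
        assert 1.5 * piWR * 0.95 < table < 2.0 * piWR * 1.05


class TestMDTraction:
    def test_support(self):
        a = 2e-7
        c = adhesive_radius(a, R, TABLE)
        assert md_traction(np.array([c * 1.0001]), a, c, R, TABLE)[0] == 0.0
        annulus = np.linspace(a * 1.0001, c * 0.9999, 7)
        np.testing.assert_allclose(md_traction(annulus, a, c, R, TABLE),
                                   -TABLE.sigma0)

    @pytest.mark.parametrize("a", [0.5e-7, 2e-7, 5e-7])
    def test_integral_matches_net_force(self, a):
        c = adhesive_radius(a, R, TABLE)
        r = np.linspace(0, c, 400001)
        F = np.trapezoid(md_traction(r, a, c, R, TABLE) * 2 * np.pi * r, r)
        assert F == pytest.approx(md_net_force(a, R, TABLE, c=c), rel=1e-4)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(a=st.floats(1e-8, 8e-7), Rr=st.floats(5e-7, 2e-5),
           W=st.floats(1e-5, 5e-3), h0=st.floats(2e-9, 2e-7))
    def test_md_state_invariants(a, Rr, W, h0):
        """For any physical contact state: c >= a, the traction vanishes
        beyond c, is -sigma0 on the annulus, and adhesion only ever reduces
        the net force below the Hertz value."""
        params = MDParams(W=W, h0=h0)
        c = adhesive_radius(a, Rr, params)
        assert c >= a
        p = md_traction(np.array([c * 1.001, (a + c) / 2]), a, c, Rr, params)
        assert p[0] == 0.0
        if c > a * 1.01:
            assert p[1] == pytest.approx(-params.sigma0)
        assert md_net_force(a, Rr, params, c=c) <= hertz_total_force(a, Rr, params)
except ImportError:          # hypothesis is an optional test dependency
    pass


class TestDetectContact:
    def test_gap_beyond_range_gives_none(self):
        tri = np.array([[0, 0, 1e-7], [1e-7, 0, 1e-7], [0, 1e-7, 1e-7]])
        geom = detect_contact(tri, np.array([0, 0, R + 50e-9]), R,
                              Plane(), TABLE)
        assert geom is None

    def test_far_fragment_of_sphere_gives_none(self):
        # triangle on top of the cell: its sphere touches the plane but the
        # physical patch is a cell diameter away
        tri = np.array([[0, 0, 2 * R], [1e-7, 0, 2 * R], [0, 1e-7, 2 * R]])
        geom = detect_contact(tri, np.array([0, 0, R]), R, Plane(), TABLE)
        assert geom is None

    def test_contacting_triangle_is_detected(self):
        tri = np.array([[0, 0, 5e-9], [2e-7, 0, 8e-9], [0, 2e-7, 8e-9]])
        geom = detect_contact(tri, np.array([0, 0, R + 5e-9]), R, Plane(), TABLE)
        assert geom is not None and geom.c > 0

    def test_sphere_sphere_intersection_circle(self):
        Rs = 1e-6
        d = 1.5e-6                       # equal spheres, overlapping
        g = sphere_sphere_geometry(np.array([0, 0, d]), Rs,
                                   np.zeros(3), Rs, MDParams(W=0.0))
        assert g.a == pytest.approx(math.sqrt(Rs**2 - d**2 / 4), rel=1e-12)
        assert g.R_red == pytest.approx(Rs / 2)


class TestQuadrature:
    @pytest.mark.parametrize("rule", [RULE_DEGREE8, RULE_DEGREE5],
                             ids=["deg8-16pt", "deg5-7pt"])
    def test_degree_exactness(self, rule):
        assert rule.weights.sum() == pytest.approx(1.0, rel=1e-13)
        for p in range(rule.degree + 1):
            for q in range(rule.degree + 1 - p):
                num = np.sum(rule.weights * rule.points[:, 0]**p
                             * rule.points[:, 1]**q)
                exact = (2.0 * math.factorial(p) * math.factorial(q)
                         / math.factorial(p + q + 2))
                # tabulated coordinates carry ~15 printed digits
                assert num == pytest.approx(exact, rel=1e-8), (p, q)

    def test_rule_sizes(self):
        assert RULE_DEGREE8.n_points == 16
        assert RULE_DEGREE5.n_points == 7


def _polar_grid_force(tri, geom, params, n_r=500, n_phi=800):
    """Oracle: mid-point polar-grid integral of the traction over
    triangle ∩ disc, independent of the quadrature path."""
    from mdcell.contact import _project_to_plane, md_traction

    uv = _project_to_plane(tri, geom)
    r_edges = np.linspace(0, geom.c, n_r + 1)
    r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    rr, pp = np.meshgrid(r_mid, phi, indexing="ij")
    px = rr * np.cos(pp)
    py = rr * np.sin(pp)
    # inside-triangle mask via barycentric coordinates
    T = np.array([uv[0] - uv[2], uv[1] - uv[2]]).T
    inv = np.linalg.inv(T)
    lam12 = np.einsum("ij,xyj->xyi", inv,
                      np.stack([px - uv[2, 0], py - uv[2, 1]], axis=-1))
    lam3 = 1 - lam12.sum(axis=-1)
    mask = (lam12 >= 0).all(axis=-1) & (lam3 >= 0)
    p = md_traction(rr.ravel(), geom.a, geom.c, geom.R_red, params).reshape(rr.shape)
    dA = rr * (r_edges[1] - r_edges[0]) * (2 * np.pi / n_phi)
    return float(np.sum(p * dA * mask))


class TestTriangleContactForce:
    def test_zero_traction_gives_zero_patch(self):
        tri = np.array([[0, 0, 1e-6], [2e-7, 0, 1e-6], [0, 2e-7, 1e-6]])
        geom = sphere_plane_geometry(np.array([0, 0, R + 10e-9]), R, Plane(),
                                     TABLE)
        # triangle footprint far outside the disc
        far = tri + np.array([10e-6, 0, 0])
        patch = triangle_contact_force(far, geom, TABLE)
        assert np.allclose(patch.F, 0) and np.allclose(patch.M, 0)
        assert patch.A_contact == 0.0

    def test_quadrature_matches_polar_grid_oracle(self, rng):
        """20 random contact states: triangle force within 1 % of a dense
        polar-grid integral of the same traction."""
        worst = 0.0
        for _ in range(20):
            delta = rng.uniform(0.002, 0.03) * R
            center = np.array([0, 0, R - delta])
            geom = sphere_plane_geometry(center, R, Plane(), TABLE)
            # random triangle near the contact zone, chord-projected
            rho0 = rng.uniform(0, geom.c * 1.1)
            ang = rng.uniform(0, 2 * np.pi)
            size = rng.uniform(0.3, 1.2) * geom.c
            p0 = np.array([rho0 * np.cos(ang), rho0 * np.sin(ang), 0.0])
            tri = p0 + np.array([[0, 0, 0],
                                 [size, 0.1 * size, 0],
                                 [0.2 * size, size, 0]])
            patch = triangle_contact_force(tri, geom, TABLE, refine_level=5)
            oracle = _polar_grid_force(tri, geom, TABLE)
            scale = max(abs(oracle), TABLE.sigma0 * np.pi * geom.c**2 * 1e-3)
            worst = max(worst, abs(float(patch.F @ geom.normal) - oracle) / scale)
        assert worst < 0.01

    def test_force_is_normal_to_contact_plane(self, rng):
        delta = 0.01 * R
        geom = sphere_plane_geometry(np.array([0, 0, R - delta]), R, Plane(),
                                     TABLE)
        tri = np.array([[0, 0, 0], [3e-7, 0, 2e-8], [0, 3e-7, 2e-8]])
        patch = triangle_contact_force(tri, geom, TABLE)
        F = patch.F
        assert abs(F @ geom.e1) < 1e-12 * np.linalg.norm(F)
        assert abs(F @ geom.e2) < 1e-12 * np.linalg.norm(F)
        assert abs(patch.M @ geom.normal) < 1e-12 * max(np.linalg.norm(patch.M), 1e-30)

    def test_continuity_across_small_contact_switch(self):
        """Force-displacement continuity where the scaled-total-force
        fallback takes over from quadrature (jump below 2 %)."""
        tri = np.array([[-2e-7, -1.5e-7, 0], [2.5e-7, -1e-7, 0],
                        [0, 2.5e-7, 0]])
        u, v = tri[1, :2] - tri[0, :2], tri[2, :2] - tri[0, :2]
        A_tri = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        params = MDParams(W=0.0)
        # find the gap where disc area crosses A_tri / N_q
        target_a = math.sqrt(A_tri / 16 / math.pi)
        delta_t = target_a**2 / (2 * R)
        ratios = []
        small_flags = []
        for eps in (0.97, 1.03):
            geom = sphere_plane_geometry(np.array([0, 0, R - delta_t * eps]),
                                         R, Plane(), params)
            patch = triangle_contact_force(tri, geom, params)
            # the disc is fully inside the triangle, so the exact result is
            # the whole-sphere Hertz force: normalise out the depth growth
            ratios.append(float(patch.F[2])
                          / hertz_total_force(geom.a, geom.R_red, params))
            small_flags.append(patch.small_contact)
        assert small_flags == [True, False]          # the switch is crossed
        assert abs(ratios[0] - ratios[1]) < 0.02


class TestDistributeToNodes:
    def _geom(self):
        return sphere_plane_geometry(np.array([0, 0, R - 0.01 * R]), R,
                                     Plane(), TABLE)

    def test_centroid_force_splits_in_thirds(self):
        geom = self._geom()
        tri = np.array([[1e-7, 0, 0], [-5e-8, 8e-8, 0], [-5e-8, -8e-8, 0]])
        F = 1e-9 * geom.normal
        f = distribute_to_nodes(F, np.zeros(3), tri, geom)
        np.testing.assert_allclose(f, np.tile(F / 3, (3, 1)), rtol=1e-9)

    def test_conservation_for_random_inputs(self, rng):
        geom = self._geom()
        for _ in range(10):
            tri = rng.uniform(-3e-7, 3e-7, (3, 3))
            tri[:, 2] = rng.uniform(0, 2e-8, 3)
            F_s = rng.uniform(-1e-9, 1e-9)
            F = F_s * geom.normal
            m12 = rng.uniform(-1e-16, 1e-16, 2)
            M = m12[0] * geom.e1 + m12[1] * geom.e2
            f = distribute_to_nodes(F, M, tri, geom)
            np.testing.assert_allclose(f.sum(axis=0), F, atol=1e-12 * abs(F_s))
            rel = tri - geom.point
            M_rec = np.cross(rel, f).sum(axis=0)
            np.testing.assert_allclose(M_rec, M,
                                       atol=1e-12 * max(np.abs(M).max(), 1e-30)
                                       + 1e-12 * abs(F_s) * 3e-7)

    def test_force_at_vertex_goes_to_that_vertex(self):
        geom = self._geom()
        P = geom.point
        tri = np.array([P, P + np.array([3e-7, 0, 0]),
                        P + np.array([0, 3e-7, 0])])
        F = 2e-9 * geom.normal
        M = np.zeros(3)
        f = distribute_to_nodes(F, M, tri, geom)
        np.testing.assert_allclose(f[0], F, atol=1e-18)
        np.testing.assert_allclose(f[1:], 0, atol=1e-18)

    def test_collinear_projection_raises(self):
        geom = self._geom()
        tri = np.array([[0, 0, 0], [1e-7, 0, 0], [2e-7, 0, 5e-8]])
        tri[2, :2] = [2e-7, 0]           # collinear in the contact plane
        with pytest.raises(np.linalg.LinAlgError):
            distribute_to_nodes(1e-9 * geom.normal, np.zeros(3), tri, geom)

    def test_contact_weights_match_unit_force_distribution(self):
        geom = self._geom()
        tri = np.array([[1.2e-7, 3e-8, 0], [-6e-8, 9e-8, 0], [-4e-8, -1e-7, 0]])
        w = contact_weights(tri, geom)
        f = distribute_to_nodes(geom.normal, np.zeros(3), tri, geom)
        np.testing.assert_allclose(w, f @ geom.normal, atol=1e-12)
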