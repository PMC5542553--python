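"""DEM forces, neighbour search and mechanical relaxation."""

import numpy as np
import pytest

from biofilmdem import (AdhesiveLinks, AgentState, Domain, MechanicsError,
                        adhesive_force, build_links, contact_force,
                        drag_force, relax, wall_contact)
from biofilmdem.agents import EPS, HET
from biofilmdem.config import mass_from_radius
from biofilmdem.mechanics import build_pairs, min_image


class TestContactForce:
    def test_separated_pair_no_force(self, p):
        F1, F2 = contact_force([0, 0, 0], [2, 0, 0], [0, 0, 0], [0, 0, 0],
                               0.5, 0.5, 1.0, 1.0, p)
        assert not F1.any() and not F2.any()

    def test_static_hookean_magnitude(self, p):
        """Overlap 0.1 um: |F| = k_n * delta."""
        F1, _ = contact_force([0, 0, 0], [0.9, 0, 0], [0, 0, 0], [0, 0, 0],
                              0.5, 0.5, 1.0, 1.0, p)
        assert np.linalg.norm(F1) == pytest.approx(p.k_n * 0.1, rel=1e-12)
        assert F1[0] < 0   # pushes i away from j

    def test_newtons_third_law(self, p, rng):
        for _ in range(20):
            xi, xj = rng.uniform(0, 2, 3), rng.uniform(0, 2, 3)
            vi, vj = rng.normal(size=3), rng.normal(size=3)
            F1, F2 = contact_force(xi, xj, vi, vj, 1.0, 1.2, 2.0, 3.0, p,
                                   delta_t=rng.normal(size=3) * 0.01)
            assert np.allclose(F1, -F2)

    def test_hertzian_scaling(self, p):
        F_hook, _ = contact_force([0, 0, 0], [0.9, 0, 0], [0, 0, 0],
                                  [0, 0, 0], 0.5, 0.5, 1.0, 1.0, p,
                                  model="hookean")
        F_hertz, _ = contact_force([0, 0, 0], [0.9, 0, 0], [0, 0, 0],
                                   [0, 0, 0], 0.5, 0.5, 1.0, 1.0, p,
                                   model="hertzian")
        f = np.sqrt(0.1 * 0.25)   # sqrt(delta * r_i r_j / (r_i + r_j))
        assert np.linalg.norm(F_hertz) == pytest.approx(
            f * np.linalg.norm(F_hook), rel=1e-12)

    def test_coincident_centres_fallback(self, p):
        with pytest.warns(UserWarning, match="coincident"):
            F1, _ = contact_force([1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0],
                                  0.5, 0.5, 1.0, 1.0, p)
        assert F1[2] > 0 and F1[0] == F1[1] == 0.0


class TestWallContact:
    def test_grazing_contact_zero(self, p):
        F = wall_contact([1, 1, 0.5], [0, 0, 0], 0.5, 1.0, p)
        assert not F.any()

    def test_overlapping_substratum_repels(self, p):
        F = wall_contact([1, 1, 0.45], [0, 0, 0], 0.5, 1.0, p)
        assert F[2] == pytest.approx(p.k_n * 0.05, rel=1e-12)

    def test_far_from_walls_zero(self, p):
        assert not wall_contact([1, 1, 10.0], [0, 0, 0], 0.5, 1.0, p,
                                L_z=40.0).any()

    def test_top_wall_pushes_down(self, p):
        F = wall_contact([1, 1, 39.6], [0, 0, 0], 0.5, 1.0, p, L_z=40.0)
        assert F[2] == pytest.approx(-p.k_n * 0.1, rel=1e-12)


class TestAdhesiveForce:
    def test_rest_length_zero_force(self, p):
        F1, F2, active = adhesive_force(1.0, 2.0, [0, 0, 0], [1, 0, 0], p.k_eps)
        assert not F1.any() and active

    def test_stretched_magnitude_attractive(self, p):
        F1, F2, active = adhesive_force(1.0, 2.0, [0, 0, 0], [1.5, 0, 0], p.k_eps)
        assert active
        assert F1[0] == pytest.approx(p.k_eps * 2.0 * 0.5, rel=1e-12)
        assert np.allclose(F1, -F2)

    def test_breaks_at_twice_rest_length(self, p):
        F1, _, active = adhesive_force(1.0, 2.0, [0, 0, 0], [2.0, 0, 0], p.k_eps)
        assert not active and not F1.any()

    def test_no_eps_mass_no_force(self, p):
        F1, _, active = adhesive_force(1.0, 0.0, [0, 0, 0], [1.5, 0, 0], p.k_eps)
        assert not active and not F1.any()


class TestDragForce:
    def test_zero_relative_velocity(self, p):
        assert not drag_force(0.5, [1, 0, 0], [1, 0, 0], p.mu_fluid).any()

    def test_stokes_magnitude(self, p):
        """mu = 1e-3 Pa s, r = 0.5 um, |v_rel| = 1 um/s."""
        F = drag_force(0.5, [0, 0, 0], [1, 0, 0], p.mu_fluid)
        assert F[0] == pytest.approx(6 * np.pi * p.mu_fluid * 0.5, rel=1e-12)

    def test_linear_in_radius(self, p):
        F1 = drag_force(0.5, [0, 0, 0], [1, 0, 0], p.mu_fluid)
        F2 = drag_force(1.0, [0, 0, 0], [1, 0, 0], p.mu_fluid)
        assert np.allclose(F2, 2 * F1)


class TestNeighbourSearch:
    def test_matches_brute_force(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 200))
            Lx, Ly = 30.0, 12.0
            pos = np.column_stack([rng.uniform(0, Lx, n),
                                   rng.uniform(0, Ly, n),
                                   rng.uniform(0, 25, n)])
            cutoff = float(rng.uniform(1.5, 5.0))
            pi, pj = build_pairs(pos, cutoff, Lx, Ly, True, True)
            got = set(zip(pi.tolist(), pj.tolist()))
            assert len(got) == pi.size   # exactly once each
            want = set()
            for i in range(n):
                for j in range(i + 1, n):
                    dx = min_image(pos[i] - pos[j], (Lx, Ly))
                    if dx @ dx <= cutoff**2:
                        want.add((i, j))
            assert got == want


class TestRelaxation:
    def test_two_spheres_relax_to_touching(self, two_overlapping, domain, p):
        res = relax(two_overlapping, AdhesiveLinks.none(), domain, p,
                    pressure_tol=1e-8, max_time=5.0)
        sep = np.linalg.norm(two_overlapping.position[0]
                             - two_overlapping.position[1])
        r = two_overlapping.radius(p)
        assert abs(sep - (r[0] + r[1])) < 1e-3 * r[0]
        assert res.converged

    def test_pressure_trace_decays(self, two_overlapping, domain, p):
        res = relax(two_overlapping, AdhesiveLinks.none(), domain, p,
                    pressure_tol=1e-8, max_time=5.0)
        peak = np.argmax(res.pressures)
        assert np.all(np.diff(res.pressures[peak:]) <= 1e-18)
        assert res.pressures[-1] < 1e-4 * res.pressures[peak]

    def test_terminal_velocity_equals_local_flow(self, domain, p):
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[20.0, 5.0, 10.0]],
                 mass_from_radius(0.5, p.rho_X))
        relax(a, AdhesiveLinks.none(), domain, p, gamma_dot=0.1,
              pressure_tol=None, max_time=0.05)
        assert a.velocity[0, 0] == pytest.approx(0.1 * a.position[0, 2],
                                                 rel=1e-6)

    def test_internal_forces_sum_to_zero(self, domain, p, rng):
        """A floating random cluster: contact + adhesion forces cancel, so
        the centre of mass stays put during force-only relaxation."""
        n = 30
        a = AgentState.empty()
        a.append(np.full(n, HET, np.int8),
                 rng.uniform(15, 22, (n, 3)) + [[0, -10, 0]],
                 mass_from_radius(0.5, p.rho_X), eps_shell=1.0)
        a.position[:, 1] = rng.uniform(3, 7, n)
        a.position[:, 2] = rng.uniform(15, 22, n)
        links = build_links(a, p, domain)
        zeta = 6 * np.pi * p.mu_fluid * a.contact_radius(p)
        com0 = (a.position * zeta[:, None]).sum(0)   # drag-weighted CoM
        relax(a, links, domain, p, pressure_tol=None, max_time=0.01,
              top_wall=False)
        com1 = (a.position * zeta[:, None]).sum(0)
        scale = np.abs(a.position).max() * zeta.max()
        assert np.all(np.abs(com1 - com0) < 1e-9 * scale)

    def test_periodic_translation_leaves_forces_unchanged(self, domain, p):
        """Rigidly shifting all agents by (L_x, 0, 0) changes nothing."""
        rng = np.random.default_rng(11)
        n = 20
        pos = np.column_stack([rng.uniform(0, domain.L_x, n),
                               rng.uniform(0, domain.L_y, n),
                               rng.uniform(0.5, 5, n)])
        out = []
        for shift in (0.0, domain.L_x):
            a = AgentState.empty()
            a.append(np.full(n, HET, np.int8), pos + [shift, 0, 0],
                     mass_from_radius(0.5, p.rho_X))
            relax(a, AdhesiveLinks.none(), domain, p, pressure_tol=1e-6,
                  max_time=0.2)
            out.append(a.position.copy())
        assert np.allclose(out[0] % domain.L_x, out[1] % domain.L_x,
                           atol=1e-9)

    def test_link_breakage_is_permanent(self, domain, p):
        """A link seen beyond 2 d0 deactivates and never re-engages within
        the relaxation phase, even if the pair comes back into range."""
        a = AgentState.empty()
        m = mass_from_radius(0.5, p.rho_EPS)
        a.append(np.array([EPS, EPS], np.int8),
                 [[10.0, 5.0, 20.0], [11.0, 5.0, 20.0]], m)
        links = build_links(a, p, domain)
        assert links.n_active == 1
        a.position[1, 0] = 10.0 + 2.1 * links.d0[0]   # beyond breakage
        relax(a, links, domain, p, pressure_tol=None, max_time=0.005,
              top_wall=False)
        assert links.n_active == 0
        a.position[1, 0] = 11.0                       # back in range
        pos_before = a.position.copy()
        relax(a, links, domain, p, pressure_tol=None, max_time=0.005,
              top_wall=False)
        assert links.n_active == 0
        # no adhesive pull: the (non-overlapping) pair does not move
        assert np.allclose(a.position, pos_before)

    def test_excessive_dt_rejected(self, two_overlapping, domain, p):
        with pytest.raises(MechanicsError, match="stability"):
            relax(two_overlapping, AdhesiveLinks.none(), domain, p,
                  dt=1e3, max_time=10.0)


class TestLinks:
    def test_links_require_eps_material(self, domain, p):
        a = AgentState.empty()
        m = mass_from_radius(0.5, p.rho_X)
        a.append(np.full(2, HET, np.int8),
                 [[10, 5, 5], [11.0, 5, 5]], m)   # touching, no EPS
        assert build_links(a, p, domain).n_active == 0
        a.eps_shell[:] = 0.5
        links = build_links(a, p, domain)
        assert links.n_active == 1
        assert links.m_eps[0] == pytest.approx(1.0)

    def test_free_eps_particle_contributes_own_mass(self, domain, p):
        a = AgentState.empty()
        m = mass_from_radius(0.5, p.rho_X)
        a.append(np.array([HET, EPS], np.int8),
                 [[10, 5, 5], [11.0, 5, 5]], m)
        links = build_links(a, p, domain)
        assert links.m_eps[0] == pytest.approx(m)
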