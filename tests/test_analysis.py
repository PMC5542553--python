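"""Morphometrics, cluster detection and detachment statistics."""

import numpy as np
import pandas as pd
import pytest

from biofilmdem import (AgentState, Domain, clusters, detachment_statistics,
                        height_field, morphology, occupancy, volume_fractions)
from biofilmdem.agents import EPS, HET, INERT
from biofilmdem.analysis import active_layer_thickness
from biofilmdem.config import mass_from_radius
from biofilmdem.mechanics import build_links


def agents_at(p, positions, group=HET, radius=0.5):
    a = AgentState.empty()
    positions = np.atleast_2d(positions)
    a.append(np.full(len(positions), group, np.int8), positions,
             mass_from_radius(radius, p.rho_X))
    return a


class TestHeightField:
    def test_empty_domain_all_zero(self, domain, p):
        assert not height_field(AgentState.empty(), domain, p).any()

    def test_single_agent_column(self, domain, p):
        a = agents_at(p, [[1.0, 1.0, 10.0]])
        h = height_field(a, domain, p)
        assert h[0, 0] == pytest.approx(10.5)
        assert h.sum() == pytest.approx(10.5)

    def test_monolayer_reads_one_micron(self, domain, p):
        xs, ys = np.meshgrid(np.arange(0.5, 40, 1.0), np.arange(0.5, 10, 1.0))
        pos = np.column_stack([xs.ravel(), ys.ravel(),
                               np.full(xs.size, 0.5)])
        h = height_field(agents_at(p, pos), domain, p)
        assert np.allclose(h, 1.0)


class TestMorphology:
    def test_flat_film_zero_roughness(self, domain):
        h = np.full((domain.N_x, domain.N_y), 7.0)
        F = np.zeros(domain.shape, bool)
        m = morphology(h, F, domain)
        assert m.roughness == 0.0 and m.mean_height == 7.0

    def test_staircase_hand_computed(self, domain):
        """Two-level height field: mean and RMS match hand arithmetic."""
        h = np.zeros((domain.N_x, domain.N_y))
        h[: domain.N_x // 2] = 4.0
        h[domain.N_x // 2:] = 8.0
        F = np.zeros(domain.shape, bool)
        m = morphology(h, F, domain)
        assert m.mean_height == pytest.approx(6.0)
        assert m.roughness == pytest.approx(2.0)

    def test_full_slab_porosity_zero(self, domain):
        hz = domain.voxel[2]
        h = np.full((domain.N_x, domain.N_y), 5 * hz)
        F = np.zeros(domain.shape, bool)
        F[:, :, :5] = True
        assert morphology(h, F, domain).porosity == pytest.approx(0.0)

    def test_checkerboard_porosity_half(self, domain):
        hz = domain.voxel[2]
        h = np.full((domain.N_x, domain.N_y), 4 * hz)
        F = np.zeros(domain.shape, bool)
        ii, jj, kk = np.indices(domain.shape)
        F[:, :, :4] = ((ii + jj + kk) % 2 == 0)[:, :, :4]
        assert morphology(h, F, domain).porosity == pytest.approx(0.5)

    def test_empty_biofilm_flagged(self, domain):
        m = morphology(np.zeros((domain.N_x, domain.N_y)),
                       np.zeros(domain.shape, bool), domain)
        assert m.degenerate and m.porosity == 0.0


class TestOccupancy:
    def test_sphere_rule_marks_intersected_voxels(self, p):
        d = Domain(L_x=9, L_y=9, L_z=9, N_x=3, N_y=3, N_z=3)
        a = agents_at(p, [[4.5, 4.5, 4.5]], radius=2.0)
        F = occupancy(a, d, p)
        assert F[1, 1, 1]
        assert F[0, 1, 1] and F[2, 1, 1]     # sphere reaches face voxels
        assert not F[0, 0, 0]                # corner voxel out of reach

    def test_centre_rule_single_voxel(self, p):
        d = Domain(L_x=9, L_y=9, L_z=9, N_x=3, N_y=3, N_z=3)
        a = agents_at(p, [[4.5, 4.5, 4.5]], radius=2.0)
        F = occupancy(a, d, p, rule="centre")
        assert F.sum() == 1 and F[1, 1, 1]


class TestVolumeFractions:
    def test_all_bacteria(self, p):
        a = agents_at(p, [[1, 1, 1], [2, 2, 2]])
        vf = volume_fractions(a, p)
        assert vf == {"bacteria": 1.0, "EPS": 0.0, "inert": 0.0}

    def test_equal_volumes_split(self, p):
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[1, 1, 1]], 2.0 * p.rho_X)
        a.append(np.array([EPS], np.int8), [[3, 1, 1]], 2.0 * p.rho_EPS)
        vf = volume_fractions(a, p)
        assert vf["bacteria"] == pytest.approx(0.5)
        assert vf["EPS"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, p, rng):
        a = AgentState.empty()
        groups = rng.choice([HET, EPS, INERT], 30).astype(np.int8)
        a.append(groups, rng.uniform(0, 10, (30, 3)), rng.uniform(1, 5, 30))
        vf = volume_fractions(a, p)
        assert sum(vf.values()) == pytest.approx(1.0)

    def test_empty_population(self, p):
        assert volume_fractions(AgentState.empty(), p) == {
            "bacteria": 0.0, "EPS": 0.0, "inert": 0.0}


class TestActiveLayer:
    def test_all_active_equals_height(self, domain, p):
        pos = [[x, 5.0, z] for x in (2.0, 6.0) for z in (0.5, 1.5, 2.5)]
        a = agents_at(p, pos)
        t = active_layer_thickness(a, np.ones(a.n), domain, p)
        assert t == pytest.approx(3.0 - 0.5)

    def test_top_monolayer_active(self, domain, p):
        pos = [[2.0, 5.0, z] for z in (0.5, 1.5, 2.5, 3.5)]
        a = agents_at(p, pos)
        rates = np.array([0.0, 0.0, 0.0, 1.0])
        t = active_layer_thickness(a, rates, domain, p, frac_threshold=0.5)
        assert t == pytest.approx(4.0 - 3.5)

    def test_no_active_cells(self, domain, p):
        a = agents_at(p, [[1, 1, 1]])
        assert active_layer_thickness(a, np.zeros(1), domain, p) == 0.0


class TestClusters:
    def test_two_touching_on_substratum(self, domain, p):
        a = agents_at(p, [[5.0, 5.0, 0.5], [6.0, 5.0, 0.5]])
        cs = clusters(a, None, domain, p)
        assert cs.n == 1 and cs.attached[0]

    def test_isolated_floater_detached(self, domain, p):
        a = agents_at(p, [[5.0, 5.0, 0.5], [20.0, 5.0, 30.0]])
        cs = clusters(a, None, domain, p)
        assert cs.n == 2
        assert sorted(cs.attached.tolist()) == [False, True]
        det = cs.detached_components()[0]
        assert cs.volumes[det] == pytest.approx(
            float(a.volume(p)[1]), rel=1e-12)

    def test_matches_brute_force_union_find(self, domain, p, rng):
        """Random 50-agent configurations: partition equals an O(n^2)
        union-find over the full pair matrix."""
        for _ in range(5):
            n = 50
            a = AgentState.empty()
            pos = np.column_stack([rng.uniform(0, domain.L_x, n),
                                   rng.uniform(0, domain.L_y, n),
                                   rng.uniform(0.5, 15, n)])
            a.append(np.full(n, HET, np.int8), pos,
                     mass_from_radius(0.5, p.rho_X))
            cs = clusters(a, None, domain, p)
            # brute force union-find
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            rc = a.contact_radius(p)
            for i in range(n):
                for j in range(i + 1, n):
                    dx = pos[i] - pos[j]
                    dx[0] -= domain.L_x * np.round(dx[0] / domain.L_x)
                    dx[1] -= domain.L_y * np.round(dx[1] / domain.L_y)
                    if np.sqrt(dx @ dx) <= (rc[i] + rc[j]) * (1 + 1e-6):
                        parent[find(i)] = find(j)
            brute = np.array([find(i) for i in range(n)])
            # same partition: labels agree up to renaming
            for c in np.unique(cs.labels):
                members = np.flatnonzero(cs.labels == c)
                assert len(set(brute[members])) == 1
            assert len(np.unique(brute)) == cs.n

    def test_invariant_to_ordering_and_translation(self, domain, p, rng):
        n = 40
        pos = np.column_stack([rng.uniform(0, domain.L_x, n),
                               rng.uniform(0, domain.L_y, n),
                               rng.uniform(0.5, 10, n)])
        a1 = agents_at(p, pos)
        perm = rng.permutation(n)
        a2 = agents_at(p, pos[perm])
        shifted = pos.copy()
        shifted[:, 0] = (shifted[:, 0] + domain.L_x / 2) % domain.L_x
        a3 = agents_at(p, shifted)
        n1 = clusters(a1, None, domain, p).n
        assert clusters(a2, None, domain, p).n == n1
        assert clusters(a3, None, domain, p).n == n1

    def test_adhesive_link_joins_separated_agents(self, domain, p):
        a = AgentState.empty()
        m = mass_from_radius(0.5, p.rho_EPS)
        a.append(np.full(2, EPS, np.int8),
                 [[5.0, 5.0, 0.5], [6.05, 5.0, 0.5]], m)
        assert clusters(a, None, domain, p).n == 2
        links = build_links(a, p, domain)
        assert clusters(a, links, domain, p).n == 1


class TestDetachmentStatistics:
    def test_single_event_rate(self):
        ev = pd.DataFrame({"time": [10.0], "volume": [5.0]})
        stats = detachment_statistics(ev, initial_volume=100.0, duration=50.0)
        assert stats["rate"] == pytest.approx(0.1)
        assert stats["n_events"] == 1
        assert stats["total_detached_fraction"] == pytest.approx(0.05)

    def test_no_events_empty_statistics(self):
        stats = detachment_statistics(pd.DataFrame(), 100.0, 10.0)
        assert stats["n_events"] == 0 and stats["rate"] == 0.0

    def test_lognormal_fit_recovers_parameters(self):
        """ML fit on 500 synthetic lognormal volumes recovers (mu, sigma)
        within a few standard errors."""
        rng = np.random.default_rng(8)
        mu, sigma, n = 1.5, 0.6, 500
        v = rng.lognormal(mu, sigma, n)
        ev = pd.DataFrame({"time": np.linspace(0, 9, n), "volume": v})
        stats = detachment_statistics(ev, initial_volume=1e4, duration=10.0)
        se_mu = sigma / np.sqrt(n)
        se_sigma = sigma / np.sqrt(2 * n)
        assert abs(stats["lognormal_mu"] - mu) < 4 * se_mu
        assert abs(stats["lognormal_sigma"] - sigma) < 4 * se_sigma

    def test_counts_binned_over_duration(self):
        ev = pd.DataFrame({"time": [1.0, 1.2, 8.0], "volume": [1, 1, 1.0]})
        stats = detachment_statistics(ev, 10.0, 10.0, n_bins=5)
        assert stats["counts"].tolist() == [2, 0, 0, 0, 1]
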