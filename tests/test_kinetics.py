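"""Monod kinetics, biomass updates and voxel uptake fields."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilmdem import (AgentState, Domain, monod, single_species_network,
                        specific_rate, step_biomass, three_species_network,
                        uptake_field)
from biofilmdem.agents import EPS, HET, INERT
from biofilmdem.config import mass_from_radius
from biofilmdem.kinetics import (agent_rates, biomass_concentrations,
                                 network_from_dict, network_to_dict)


class TestMonod:
    def test_half_saturation(self):
        assert monod(3.5e-5, 3.5e-5) == pytest.approx(0.5)

    def test_zero_substrate(self):
        assert monod(0.0, 1e-5) == 0.0

    def test_bulk_value_hand_computed(self):
        # S_b / (K_S + S_b) = 1e-4 / 1.35e-4
        assert monod(1e-4, 3.5e-5) == pytest.approx(1e-4 / 1.35e-4, rel=1e-12)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            monod(-1.0, 1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(S1=st.floats(0, 1e-2), S2=st.floats(0, 1e-2),
           K=st.floats(1e-8, 1e-2))
    def test_bounded_and_monotone(self, S1, S2, K):
        m1, m2 = monod(S1, K), monod(S2, K)
        assert 0.0 <= m1 < 1.0
        if S1 < S2:
            assert m1 <= m2


class TestSpecificRate:
    def test_starved_heterotroph_decays_at_b(self, p):
        net = single_species_network(p)
        assert specific_rate(HET, {"S_S": 0.0}, net) == pytest.approx(-p.b)

    def test_saturated_growth_approaches_mu_m(self, p):
        net = single_species_network(p)
        r = specific_rate(HET, {"S_S": 1e3}, net)
        assert r == pytest.approx(p.mu_m - p.b, rel=1e-6)

    def test_inert_without_decay_is_zero(self, p):
        net = single_species_network(p)   # inert decay defaults to 0
        assert specific_rate(INERT, {"S_S": 1e-4}, net) == 0.0

    def test_monotone_in_substrate(self, p):
        net = single_species_network(p)
        rates = [specific_rate(HET, {"S_S": s}, net)
                 for s in np.linspace(0, 5e-4, 30)]
        assert np.all(np.diff(rates) > 0)

    def test_network_round_trips_through_dict(self, p):
        net = three_species_network(p)
        net2 = network_from_dict(network_to_dict(net))
        assert network_to_dict(net2) == network_to_dict(net)


class TestStepBiomass:
    def test_zero_rate_leaves_mass_unchanged(self, p):
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[1, 1, 1]], 10.0)
        step_biomass(a, np.zeros(1), np.zeros(1), 1000.0)
        assert a.mass[0] == 10.0

    def test_small_steps_match_exponential(self, p):
        """Euler integration over 10 h at dt = 100 s stays within 1% of
        m0 exp(rt) at moderate Monod saturation (at full saturation the
        scheme's truncation bias alone exceeds 1%)."""
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[1, 1, 1]], 5.0)
        net = single_species_network(p)
        r = specific_rate(HET, {"S_S": p.K_S / 4.0}, net)
        assert r > 0
        for _ in range(360):
            step_biomass(a, np.array([r]), np.zeros(1), 100.0)
        exact = 5.0 * np.exp(r * 36000.0)
        assert a.mass[0] == pytest.approx(exact, rel=0.01)

    def test_total_mass_change_is_linear_in_rates(self, p, rng):
        n = 20
        a = AgentState.empty()
        a.append(np.full(n, HET, np.int8), rng.uniform(0, 10, (n, 3)),
                 rng.uniform(1, 5, n))
        m0 = a.mass.copy()
        r = rng.uniform(-1e-4, 1e-4, n)
        step_biomass(a, r, np.zeros(n), 50.0)
        assert np.sum(a.mass - m0) == pytest.approx(np.sum(m0 * r * 50.0))

    def test_nonpositive_mass_flagged_not_raised(self, p):
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[1, 1, 1]], 1.0)
        flagged = step_biomass(a, np.array([-1.0]), np.zeros(1), 10.0)
        assert flagged[0] and a.mass[0] > 0

    def test_shell_accrual_fraction(self, p):
        """EPS shell gains Y_EPS/Y per unit of substrate-derived growth."""
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[1, 1, 1]], 10.0)
        net = single_species_network(p)
        r_net, r_shell = agent_rates(a, {"S_S": np.array([p.S_b])}, net)
        growth_only = r_net[0] + p.b     # subtract decay
        assert r_shell[0] / growth_only == pytest.approx(p.Y_EPS / p.Y)


class TestUptakeField:
    def test_empty_domain_has_zero_uptake(self, p, domain):
        net = single_species_network(p)
        R = uptake_field(AgentState.empty(), domain, net,
                         {"S_S": np.full(domain.shape, p.S_b)})
        assert not np.any(R["S_S"])

    def test_single_agent_matches_hand_evaluation(self, p, domain):
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[1.0, 1.0, 1.0]], 12.0)
        net = single_species_network(p)
        S = np.full(domain.shape, p.S_b)
        R = uptake_field(a, domain, net, {"S_S": S})
        X = 12.0 / domain.voxel_volume
        expected = -(1.0 / p.Y) * p.mu_m * monod(p.S_b, p.K_S) * X
        assert R["S_S"][0, 0, 0] == pytest.approx(expected, rel=1e-12)
        assert R["S_S"][0, 0, 0] < 0

    def test_uptake_linear_in_biomass(self, p, domain):
        net = single_species_network(p)
        S = {"S_S": np.full(domain.shape, p.S_b)}
        a1 = AgentState.empty()
        a1.append(np.array([HET], np.int8), [[1, 1, 1]], 10.0)
        a2 = AgentState.empty()
        a2.append(np.array([HET], np.int8), [[1, 1, 1]], 20.0)
        R1 = uptake_field(a1, domain, net, S)["S_S"][0, 0, 0]
        R2 = uptake_field(a2, domain, net, S)["S_S"][0, 0, 0]
        assert R2 == pytest.approx(2 * R1, rel=1e-12)

    def test_shell_mass_counts_as_eps_phase(self, p, domain):
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[1, 1, 1]], 10.0, eps_shell=4.0)
        X = biomass_concentrations(a, domain)
        vv = domain.voxel_volume
        assert X["HET"][0, 0, 0] == pytest.approx(10.0 / vv)
        assert X["EPS"][0, 0, 0] == pytest.approx(4.0 / vv)


class TestYieldConsistency:
    def test_closed_voxel_cod_balance(self, p):
        """In a closed single-voxel system, new COD (biomass + shell) per
        unit substrate consumed equals Y + Y_EPS as configured."""
        d = Domain(L_x=4, L_y=4, L_z=4, N_x=1, N_y=1, N_z=1,
                   nutrient_feed="none")
        a = AgentState.empty()
        a.append(np.array([HET], np.int8), [[2, 2, 2]],
                 mass_from_radius(0.5, p.rho_X))
        net = single_species_network(p)
        S = p.S_b
        dt = 50.0
        for _ in range(40):
            cod0 = a.total_mass()
            R = uptake_field(a, d, net, {"S_S": np.full((1, 1, 1), S)})
            r_net, r_shell = agent_rates(a, {"S_S": np.array([S])}, net)
            # remove decay to isolate the substrate-driven yield
            r_net = r_net + p.b
            step_biomass(a, r_net, r_shell, dt)
            dS = R["S_S"][0, 0, 0] * dt
            S = max(S + dS, 0.0)
            d_cod = a.total_mass() - cod0
            consumed = -dS * d.voxel_volume
            assert d_cod == pytest.approx(
                consumed * (p.Y + p.Y_EPS), rel=1e-6)
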