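from dataclasses import replace

import numpy as np
import pytest

from itamnet.constructs import (
    ConcentrationTotals,
    RateSet,
    build_chain_spec,
    preset_construct,
)
from itamnet.network import Reaction, ReactionNetwork, Species, generate_network
from itamnet.steady_state import (
    SteadyState,
    build_rate_system,
    initial_state,
    observable,
    solve_steady_state,
)

from _oracle import single_itam_phospho_oracle


class TestRateSystem:
    def test_conservation_rows_annihilate_stoichiometry(self, z123_system):
        assert np.all(z123_system.conservation @ z123_system.stoichiometry == 0)

    def test_dimensions(self, z123_system):
        assert z123_system.stoichiometry.shape == (53, 168)
        assert z123_system.conservation.shape == (4, 53)

    def test_empty_chain_has_zero_vector_field(self, totals):
        net = generate_network(build_chain_spec([], "sequential"))
        sys_ = build_rate_system(net)
        state = solve_steady_state(sys_, totals)
        assert state.residual_norm == 0.0
        c = np.random.default_rng(0).uniform(0, 1, sys_.n_species)
        assert np.all(sys_.rhs(c) == 0)

    def test_reversible_binding_pair_matches_closed_form(self):
        """A+B <-> AB fed as a hand-built 3-species network."""
        a = Species("kinase")
        b = Species("chain")
        ab = Species("chain", enzyme=("kinase", 0))
        k_on, k_off = 0.37, 2.2
        net = ReactionNetwork(
            spec=build_chain_spec([{"label": "i", "zap_koff": 1.0}]),
            species=[b, ab, a],
            reactions=[
                Reaction((b, a), (ab,), k_on, "kinase_bind"),
                Reaction((ab,), (b, a), k_off, "kinase_unbind"),
            ],
        )
        sys_ = build_rate_system(net)
        c = np.array([0.3, 0.2, 0.5])
        flux = k_on * c[0] * c[2] - k_off * c[1]
        expected = np.array([-flux, flux, -flux])
        assert np.allclose(sys_.rhs(c), expected, atol=1e-15)
        assert np.allclose(sys_.jacobian(c) @ np.eye(3), sys_.jacobian(c))


class TestSolve:
    def test_no_kinase_means_no_phosphorylation(self, z123_network, z123_system):
        state = solve_steady_state(
            z123_system, ConcentrationTotals(kinase_total=0.0)
        )
        assert observable(state, z123_network, "total_phosphorylation") < 1e-10
        assert observable(state, z123_network, "bound_zap") < 1e-10

    def test_no_phosphatase_saturates_zap(self, z123_network, z123_system):
        """With F -> 0 and ZAP in excess, all three ITAMs end ZAP-loaded."""
        totals = ConcentrationTotals(phosphatase_total=1e-10, zap_total=50.0)
        state = solve_steady_state(z123_system, totals)
        per_chain = observable(state, z123_network, "bound_zap") / totals.chain_total
        assert per_chain == pytest.approx(3.0, rel=1e-3)

    def test_single_itam_matches_reduced_model_oracle(self):
        spec = build_chain_spec(
            [{"label": "i", "zap_koff": 1.0}], zap_enabled=False
        )
        rates = RateSet()
        net = generate_network(spec, rates)
        sys_ = build_rate_system(net)
        for F in (0.3, 1.0, 3.0):
            totals = ConcentrationTotals(phosphatase_total=F)
            state = solve_steady_state(sys_, totals)
            ours = observable(state, net, "total_phosphorylation")
            theirs = single_itam_phospho_oracle(
                rates, totals.chain_total, totals.kinase_total, F
            )
            assert ours == pytest.approx(theirs, rel=1e-6)

    def test_conservation_and_positivity_contract(self, z123_system, totals):
        state = solve_steady_state(z123_system, totals)
        assert np.all(state.conservation_residuals <= 1e-6)
        assert np.all(state.concentrations >= 0)
        assert np.all(state.raw >= -1e-12)

    def test_path_independence(self, z123_network, z123_system, totals):
        """No hysteresis: the fully loaded start relaxes to the same state."""
        from_rest = solve_steady_state(z123_system, totals)
        # start fully phosphorylated and fully ZAP-loaded instead
        c0 = np.zeros(z123_system.n_species)
        for i, sp in enumerate(z123_network.species):
            if sp.kind == "chain" and sp.sites == 0b111111 and sp.zap == 0b111 and sp.enzyme is None:
                c0[i] = totals.chain_total
            elif sp.kind == "kinase":
                c0[i] = totals.kinase_total
            elif sp.kind == "phosphatase":
                c0[i] = totals.phosphatase_total
            elif sp.kind == "zap":
                c0[i] = totals.zap_total - 3 * totals.chain_total
        loaded = solve_steady_state(z123_system, totals, x0=c0)
        scale = max(totals.zap_total, 1.0)
        assert np.allclose(loaded.concentrations, from_rest.concentrations,
                           atol=1e-7 * scale)

    def test_warm_start_agrees_with_cold_start(self, z123_system, totals):
        cold = solve_steady_state(z123_system, totals)
        nearby = solve_steady_state(
            z123_system, replace(totals, phosphatase_total=totals.phosphatase_total * 1.1)
        )
        warm = solve_steady_state(z123_system, totals, x0=nearby.raw)
        assert np.allclose(warm.concentrations, cold.concentrations, atol=1e-7)

    def test_bound_zap_limit_is_monotone_in_F(self, z123_network, z123_system):
        values = []
        for F in (3.0, 1.0, 0.3, 0.1, 0.01):
            state = solve_steady_state(
                z123_system, ConcentrationTotals(phosphatase_total=F, zap_total=50.0)
            )
            values.append(observable(state, z123_network, "bound_zap"))
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] <= 3 * 0.5 + 1e-6


class TestObservable:
    def test_fully_phosphorylated_species_counts_six_phosphates(self, z123_network):
        c = np.zeros(z123_network.n_species)
        target = Species("chain", sites=0b111111)
        c[z123_network.index[target]] = 0.25
        state = SteadyState(c, 0.0, np.zeros(4), c)
        assert observable(state, z123_network, "total_phosphorylation") == pytest.approx(1.5)
        assert observable(state, z123_network, "bound_zap") == 0.0

    def test_weighted_zap_sum(self, z123_network):
        c = np.zeros(z123_network.n_species)
        one_zap = Species("chain", sites=0b000011, zap=0b001)
        three_zap = Species("chain", sites=0b111111, zap=0b111)
        c[z123_network.index[one_zap]] = 0.25
        c[z123_network.index[three_zap]] = 0.25
        state = SteadyState(c, 0.0, np.zeros(4), c)
        assert observable(state, z123_network, "bound_zap") == pytest.approx(1.0)

    def test_unknown_observable_raises(self, z123_network):
        state = SteadyState(np.zeros(53), 0.0, np.zeros(4), np.zeros(53))
        with pytest.raises(Exception, match="observable"):
            observable(state, z123_network, "bogus")
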