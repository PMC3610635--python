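import itertools

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from itamnet.constructs import RateSet, build_chain_spec, preset_construct
from itamnet.network import (
    Species,
    export_netlist,
    export_sbml,
    generate_network,
    import_netlist,
    network_summary,
    species_from_name,
)

from _oracle import brute_force_reactions, brute_force_species


def _chain(n, scheme, zap=True, koffs=None):
    koffs = koffs or [10.0 / 10**k for k in range(n)]
    return build_chain_spec(
        [{"label": f"i{k}", "zap_koff": koffs[k]} for k in range(n)],
        scheme=scheme,
        zap_enabled=zap,
        name=f"chain{n}_{scheme}",
    )


class TestEnumeration:
    def test_wild_type_counts(self, z123_network):
        assert z123_network.n_species == 53
        assert z123_network.n_reactions == 168

    def test_two_itam_counts(self):
        net = generate_network(preset_construct("zX23"))
        assert (net.n_species, net.n_reactions) == (25, 56)

    def test_single_itam_counts(self):
        net = generate_network(preset_construct("zXX3"))
        assert (net.n_species, net.n_reactions) == (11, 14)
        summary = network_summary(net)
        assert summary["by_rule"] == {
            "kinase_bind": 2, "kinase_unbind": 2, "kinase_cat": 2,
            "phosphatase_bind": 2, "phosphatase_unbind": 2, "phosphatase_cat": 2,
            "zap_bind": 1, "zap_unbind": 1,
        }

    def test_empty_chain(self):
        net = generate_network(_chain(0, "sequential"))
        assert (net.n_species, net.n_reactions) == (4, 0)

    def test_random_scheme_exceeds_500_species(self):
        net = generate_network(preset_construct("z123_random"))
        assert net.n_species > 500

    def test_no_duplicate_species_or_reactions(self, z123_network):
        assert len(set(z123_network.species)) == z123_network.n_species
        assert len(set(z123_network.reactions)) == z123_network.n_reactions

    def test_species_closed_under_reactions(self, z123_network):
        known = set(z123_network.species)
        for rxn in z123_network.reactions:
            assert set(rxn.reactants) <= known and set(rxn.products) <= known


class TestOracleEquivalence:
    """Full set equality against the literal nested-loop generator."""

    @pytest.mark.parametrize("n", [0, 1, 2])
    @pytest.mark.parametrize("scheme", ["sequential", "random"])
    @pytest.mark.parametrize("zap", [True, False])
    def test_small_chains_match_oracle(self, n, scheme, zap):
        spec = _chain(n, scheme, zap)
        rates = RateSet()
        net = generate_network(spec, rates)
        assert set(net.species) == brute_force_species(spec)
        assert set(net.reactions) == brute_force_reactions(spec, rates)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n=st.integers(0, 2),
        scheme=st.sampled_from(["sequential", "random"]),
        koffs=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=2),
    )
    def test_arbitrary_koffs_match_oracle(self, n, scheme, koffs):
        spec = _chain(n, scheme, koffs=koffs[:n] if n else None)
        rates = RateSet()
        net = generate_network(spec, rates)
        assert set(net.species) == brute_force_species(spec)
        assert set(net.reactions) == brute_force_reactions(spec, rates)


class TestStructuralProperties:
    @pytest.mark.parametrize("name", ["z123", "zX23", "zXX3"])
    def test_bind_unbind_pairing(self, name):
        summary = network_summary(generate_network(preset_construct(name)))
        by_rule = summary["by_rule"]
        for mol in ("zap", "kinase", "phosphatase"):
            assert by_rule[f"{mol}_bind"] == by_rule[f"{mol}_unbind"]

    def test_monotone_growth_with_itams(self):
        counts = []
        for n in range(4):
            net = generate_network(_chain(n, "sequential"))
            counts.append((net.n_species, net.n_reactions))
        assert counts == sorted(counts)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_strongly_connected_through_reverse_reactions(self, n):
        """Every species reaches, and is reachable from, the resting state."""
        net = generate_network(_chain(n, "sequential"))
        g = nx.DiGraph()
        chain_nodes = [s for s in net.species if s.kind == "chain"]
        g.add_nodes_from(chain_nodes)
        for rxn in net.reactions:
            src = [s for s in rxn.reactants if s.kind == "chain"]
            dst = [s for s in rxn.products if s.kind == "chain"]
            if src and dst:
                g.add_edge(src[0], dst[0])
        assert nx.is_strongly_connected(g)


class TestExport:
    def test_netlist_round_trip(self, tmp_path):
        spec = preset_construct("zX23")
        net = generate_network(spec)
        path = tmp_path / "net.tsv"
        export_netlist(net, path)
        back = import_netlist(path, spec)
        assert back.species == net.species
        assert back.reactions == net.reactions

    def test_netlist_round_trip_random_scheme(self, tmp_path):
        spec = _chain(2, "random")
        net = generate_network(spec)
        path = tmp_path / "net.tsv"
        export_netlist(net, path)
        back = import_netlist(path, spec)
        assert back.species == net.species
        assert back.reactions == net.reactions

    def test_species_name_round_trip(self, z123_network):
        n = z123_network.spec.n_sites
        for sp in z123_network.species:
            assert species_from_name(sp.name(n)) == sp

    def test_sbml_element_counts(self, tmp_path, z123_network):
        import xml.etree.ElementTree as ET

        path = tmp_path / "model.xml"
        export_sbml(z123_network, path)
        tree = ET.parse(path)
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        assert len(tree.findall(".//s:species", ns)) == 53
        assert len(tree.findall(".//s:reaction", ns)) == 168

    def test_sbml_empty_chain(self, tmp_path):
        import xml.etree.ElementTree as ET

        net = generate_network(_chain(0, "sequential"))
        path = tmp_path / "model.xml"
        export_sbml(net, path)
        tree = ET.parse(path)
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        assert len(tree.findall(".//s:species", ns)) == 4
        assert len(tree.findall(".//s:reaction", ns)) == 0
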